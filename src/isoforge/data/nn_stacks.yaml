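# Nearest-neighbor RNA/RNA helix parameters, delta-G at 37 C in kcal/mol.
#
# Keys are dinucleotide steps written as XY/ZW: top strand 5'-X Y-3' with
# partners Z (of X) and W (of Y) on the antiparallel bottom strand.  All 36
# ordered Watson-Crick / G.U wobble steps are listed explicitly.  Values were
# measured from two-base-pair duplex energies evaluated with ViennaRNA
# (Turner 2004 rule set) by subtracting the duplex initiation term and the
# terminal AU/GU penalties; Watson-Crick entries agree with the published
# Turner 2004 stack table to 0.1 kcal/mol.
table_version: nn-rna-turner2004-derived-v1
units: kcal/mol
initiation: 4.10
terminal_au_gu_penalty: 0.50
stacks:
  AA/UU: -0.9
  AU/UA: -1.1
  AG/UC: -2.1
  AC/UG: -2.2
  AG/UU: -0.6
  AU/UG: -1.4
  UA/AU: -1.3
  UU/AA: -0.9
  UG/AC: -2.1
  UC/AG: -2.4
  UG/AU: -1.0
  UU/AG: -1.3
  GA/CU: -2.4
  GU/CA: -2.2
  GG/CC: -3.3
  GC/CG: -3.4
  GG/CU: -1.5
  GU/CG: -2.5
  CA/GU: -2.1
  CU/GA: -2.1
  CG/GC: -2.4
  CC/GG: -3.3
  CG/GU: -1.4
  CU/GG: -2.1
  GA/UU: -1.3
  GU/UA: -1.4
  GG/UC: -2.1
  GC/UG: -2.5
  GG/UU: -0.5
  GU/UG: 1.3
  UA/GU: -1.0
  UU/GA: -0.6
  UG/GC: -1.4
  UC/GG: -1.5
  UG/GU: 0.3
  UU/GG: -0.5
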