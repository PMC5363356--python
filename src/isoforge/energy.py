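"""Nearest-neighbor free-energy model for miRNA:site duplexes.

The duplex ΔG is the duplex-initiation penalty plus the sum of
nearest-neighbor stacking increments over a contiguous, perfectly paired
helix, plus terminal penalties for helix ends closed by A-U or G-U pairs.
Parameters ship as a versioned YAML table (see ``data/nn_stacks.yaml``);
alternative parameterizations can be loaded through :class:`EnergyModel`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})
PAIRABLE = WATSON_CRICK | WOBBLE


def pairs(a: str, b: str, allow_gu: bool = True) -> bool:
    """Whether bases a (top strand) and b (bottom strand) can pair."""
    return (a, b) in (PAIRABLE if allow_gu else WATSON_CRICK)


@dataclass(frozen=True)
class EnergyModel:
    """Stacking parameter set, kcal/mol; negative increments stabilize."""

    stack_table: dict[str, float]
    initiation: float
    terminal_penalty: float
    table_version: str

    def __post_init__(self) -> None:
        bases = "ACGU"
        for x in bases:
            for y in bases:
                for z in bases:
                    for w in bases:
                        if (x, z) in PAIRABLE and (y, w) in PAIRABLE:
                            key = f"{x}{y}/{z}{w}"
                            if key not in self.stack_table:
                                raise ValueError(f"stack table missing step {key}")

    def stack(self, top: str, bottom: str) -> float:
        """Increment for the step 5'-top-3' over its bottom-strand partners."""
        return self.stack_table[f"{top}/{bottom}"]

    @classmethod
    def default(cls) -> "EnergyModel":
        text = resources.files("isoforge.data").joinpath("nn_stacks.yaml").read_text()
        raw = yaml.safe_load(text)
        return cls(
            stack_table={str(k): float(v) for k, v in raw["stacks"].items()},
            initiation=float(raw["initiation"]),
            terminal_penalty=float(raw["terminal_au_gu_penalty"]),
            table_version=str(raw["table_version"]),
        )


def helix_delta_g(top: str, bottom: str, model: EnergyModel) -> float:
    """ΔG of a fully paired helix: top strand 5'->3' against the antiparallel
    bottom strand given 3'->5' (``bottom[i]`` pairs ``top[i]``)."""
    if len(top) != len(bottom) or not top:
        raise ValueError("helix strands must be non-empty and equal length")
    for a, b in zip(top, bottom):
        if not pairs(a, b):
            raise ValueError(f"unpairable bases {a}-{b} in helix")
    dg = model.initiation
    for i in range(len(top) - 1):
        dg += model.stack(top[i : i + 2], bottom[i : i + 2])
    for end in (0, len(top) - 1):
        if (top[end], bottom[end]) in (WOBBLE | {("A", "U"), ("U", "A")}):
            dg += model.terminal_penalty
    return round(dg, 10)
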