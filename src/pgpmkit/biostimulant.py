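"""Prebiotic (biostimulant) suitability scoring for consortia.

Four bioactive compounds — sugar-cane molasses (BS1), yeast-autolysate protein
hydrolysate (BS2), cheese-whey protein hydrolysate (BS3) and brewery
by-products (BS4) — were screened for their ability to support each consortium
strain under starvation.  Each (strain, compound) response is qualitative:
``+`` (growth improved over the water-agar control), ``-`` (no improvement) or
``nc`` (not discriminable).  A consortium-level score for a compound is the
fraction of its table-listed members responding ``+``; ``nc`` earns no credit
but stays in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["COMPOUNDS", "BiostimulantTable", "CompoundScore", "score_compound", "rank_compounds"]

COMPOUNDS = ("BS1", "BS2", "BS3", "BS4")
_VALID = frozenset({"+", "-", "nc"})


class BiostimulantTable:
    """Strain x compound response matrix with values in {+, -, nc}."""

    def __init__(self, responses: pd.DataFrame):
        missing = set(COMPOUNDS) - set(responses.columns)
        if missing:
            raise ValueError(f"missing compound columns {sorted(missing)}")
        bad = set(responses[list(COMPOUNDS)].to_numpy().ravel()) - _VALID
        if bad:
            raise ValueError(f"invalid response values {sorted(bad)}")
        self.responses = responses[list(COMPOUNDS)]

    @property
    def strains(self) -> list[str]:
        return list(self.responses.index)

    def response(self, strain: str, compound: str) -> str:
        if compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {compound!r}")
        return self.responses.loc[strain, compound]

    def positive_count(self, compound: str) -> int:
        if compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {compound!r}")
        return int((self.responses[compound] == "+").sum())


@dataclass
class CompoundScore:
    compound: str
    fraction_positive: float
    breakdown: dict[str, str] = field(default_factory=dict)  # member -> response
    missing_members: list[str] = field(default_factory=list)

    @property
    def n_positive(self) -> int:
        return sum(v == "+" for v in self.breakdown.values())

    @property
    def n_unclear(self) -> int:
        return sum(v == "nc" for v in self.breakdown.values())


def score_compound(consortium, table: BiostimulantTable, compound: str) -> CompoundScore:
    """Fraction of consortium members with a ``+`` response to ``compound``.

    Members absent from the response table are reported in
    ``missing_members`` and excluded from the denominator.
    """
    if compound not in COMPOUNDS:
        raise ValueError(f"unknown compound {compound!r}")
    members = list(consortium.members)
    present = [m for m in members if m in table.responses.index]
    missing = [m for m in members if m not in table.responses.index]
    if not present:
        raise ValueError(
            f"no member of consortium {consortium.name!r} appears in the response table"
        )
    breakdown = {m: table.response(m, compound) for m in present}
    n_pos = sum(v == "+" for v in breakdown.values())
    return CompoundScore(
        compound=compound,
        fraction_positive=n_pos / len(present),
        breakdown=breakdown,
        missing_members=missing,
    )


def rank_compounds(consortium, table: BiostimulantTable) -> list[CompoundScore]:
    """All compounds scored and ordered for a consortium.

    Order: positive fraction descending, then fewer ``nc`` responses, then
    compound id.  An all-``nc`` compound therefore ranks behind an all-``-``
    one of equal (zero) fraction.
    """
    scores = [score_compound(consortium, table, c) for c in COMPOUNDS]
    scores.sort(key=lambda s: (-s.fraction_positive, s.n_unclear, s.compound))
    return scores
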