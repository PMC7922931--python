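"""Compatibility graphs and synthetic-consortium design.

A microbial consortium here is a set of strains that (i) can pairwise coexist
on agar (compatibility ``+``; an inhibition halo scores ``-``; neither outcome
scores ``nc``, "not clear") and (ii) jointly covers a required set of
plant-beneficial functions (nitrogen fixation, P solubilization, biocontrol,
amylolytic activity, auxin production, ...). Candidate consortia are the
inclusion-maximal cliques of the pairwise-compatibility graph, restricted to
the strains short-listed for in vitro testing and filtered by size and by
function coverage.

Two policies interpret the three-valued compatibility relation:

``strict``
    only ``+`` pairs may coexist; ``nc`` blocks.
``lenient``
    ``+`` and ``nc`` may coexist; only ``-`` blocks.  This is the default:
    one published consortium contains a pair whose fungal-plate test was
    inconclusive, so the strict reading would reject it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "COMPATIBLE",
    "INCOMPATIBLE",
    "UNCLEAR",
    "Strain",
    "CompatibilityMatrix",
    "Consortium",
    "ValidationReport",
    "build_graph",
    "validate_consortium",
    "enumerate_consortia",
]

COMPATIBLE = "+"
INCOMPATIBLE = "-"
UNCLEAR = "nc"
_VALID = frozenset({COMPATIBLE, INCOMPATIBLE, UNCLEAR})

#: tags a consortium is expected to cover, as normalised from strain properties
FUNCTION_TAGS = frozenset(
    {
        "nitrogen_fixation",
        "P_solubilization",
        "biocontrol",
        "amylolytic",
        "IAA_production",
        "siderophore",
        "phytase",
        "PGP_generic",
    }
)


class CompatibilityConflictError(ValueError):
    """Conflicting values supplied for the same unordered strain pair."""


@dataclass(frozen=True)
class Strain:
    canonical_name: str
    aliases: frozenset[str] = frozenset()
    kingdom: str = "bacterium"  # bacterium | yeast | fungus
    functions: frozenset[str] = frozenset()
    selected: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kingdom not in {"bacterium", "yeast", "fungus"}:
            raise ValueError(f"unknown kingdom {self.kingdom!r}")
        unknown = self.functions - FUNCTION_TAGS
        if unknown:
            raise ValueError(f"unknown function tags {sorted(unknown)}")


class CompatibilityMatrix:
    """Symmetric (strain, strain) -> {+, -, nc} relation.

    Entries are stored once per unordered pair; queries in either order return
    the same value.  The diagonal is ``+`` by convention (self-compatibility is
    never assayed and is biologically vacuous).  Pairs never assayed return
    ``None`` ("missing").
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], str] = {}
        self.strains: set[str] = set()

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, value: str) -> None:
        if value not in _VALID:
            raise ValueError(f"compatibility value must be one of {sorted(_VALID)}, got {value!r}")
        if a == b:
            raise ValueError("diagonal entries are fixed to '+' and cannot be set")
        key = self._key(a, b)
        existing = self._entries.get(key)
        if existing is not None and existing != value:
            raise CompatibilityConflictError(
                f"conflicting entries for pair {key}: {existing!r} vs {value!r}"
            )
        self._entries[key] = value
        self.strains.update((a, b))

    def get(self, a: str, b: str) -> str | None:
        if a == b:
            return COMPATIBLE
        return self._entries.get(self._key(a, b))

    def pairs(self):
        """Iterate over (strain_a, strain_b, value), a < b lexicographically."""
        return ((a, b, v) for (a, b), v in sorted(self._entries.items()))

    def update(self, other: "CompatibilityMatrix") -> None:
        for a, b, v in other.pairs():
            self.set(a, b, v)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return a == b or self._key(a, b) in self._entries


@dataclass(frozen=True)
class Consortium:
    """A named strain set with the policy under which it was designed."""

    name: str
    members: tuple[str, ...]
    policy: str = "lenient"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a consortium needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members")
        if self.policy not in {"strict", "lenient"}:
            raise ValueError(f"unknown policy {self.policy!r}")


@dataclass
class ValidationReport:
    consortium: str
    pair_verdicts: dict[tuple[str, str], str] = field(default_factory=dict)
    incompatible_pairs: list[tuple[str, str]] = field(default_factory=list)
    unclear_pairs: list[tuple[str, str]] = field(default_factory=list)
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)
    function_coverage: dict[str, list[str]] = field(default_factory=dict)
    uncovered_functions: list[str] = field(default_factory=list)
    passes_strict: bool = False
    passes_lenient: bool = False

    def to_dict(self) -> dict:
        return {
            "consortium": self.consortium,
            "pair_verdicts": {f"{a} | {b}": v for (a, b), v in sorted(self.pair_verdicts.items())},
            "incompatible_pairs": [list(p) for p in self.incompatible_pairs],
            "unclear_pairs": [list(p) for p in self.unclear_pairs],
            "missing_pairs": [list(p) for p in self.missing_pairs],
            "function_coverage": self.function_coverage,
            "uncovered_functions": self.uncovered_functions,
            "passes_strict": self.passes_strict,
            "passes_lenient": self.passes_lenient,
        }


def _edge_values(policy: str) -> frozenset[str]:
    if policy == "strict":
        return frozenset({COMPATIBLE})
    if policy == "lenient":
        return frozenset({COMPATIBLE, UNCLEAR})
    raise ValueError(f"unknown policy {policy!r}")


def build_graph(
    matrix: CompatibilityMatrix,
    policy: str = "lenient",
    strains: set[str] | None = None,
) -> nx.Graph:
    """Build the undirected coexistence graph under a policy.

    Nodes are strains (optionally restricted to ``strains``); an edge joins two
    strains whose compatibility entry permits coexistence under the policy.
    Assayed-but-missing pairs get no edge and are listed in
    ``graph.graph["missing_pairs"]``.
    """
    edge_ok = _edge_values(policy)
    nodes = set(matrix.strains) if strains is None else set(strains)
    g = nx.Graph(policy=policy)
    g.add_nodes_from(sorted(nodes))
    missing = []
    for a, b in itertools.combinations(sorted(nodes), 2):
        value = matrix.get(a, b)
        if value is None:
            missing.append((a, b))
        elif value in edge_ok:
            g.add_edge(a, b, compatibility=value)
    g.graph["missing_pairs"] = missing
    return g


def validate_consortium(
    consortium: Consortium,
    matrix: CompatibilityMatrix,
    strain_table: dict[str, Strain] | None = None,
    required_functions: set[str] | None = None,
    strict_missing: bool = False,
) -> ValidationReport:
    """Score every unordered member pair and report pass/fail per policy.

    ``passes_strict`` requires every pair scored ``+`` (missing pairs block
    only when ``strict_missing``); ``passes_lenient`` requires merely the
    absence of ``-`` pairs.  Function coverage is informational: the report
    lists which member covers each required function and which functions are
    uncovered, but coverage never flips the pass flags.
    """
    if strain_table is not None:
        unresolved = [m for m in consortium.members if m not in strain_table]
        if unresolved:
            raise KeyError(f"unresolvable consortium members: {unresolved}")
    report = ValidationReport(consortium=consortium.name)
    for a, b in itertools.combinations(sorted(consortium.members), 2):
        value = matrix.get(a, b)
        if value is None:
            report.pair_verdicts[(a, b)] = "missing"
            report.missing_pairs.append((a, b))
        else:
            report.pair_verdicts[(a, b)] = value
            if value == INCOMPATIBLE:
                report.incompatible_pairs.append((a, b))
            elif value == UNCLEAR:
                report.unclear_pairs.append((a, b))
    no_incompatible = not report.incompatible_pairs
    report.passes_lenient = no_incompatible
    report.passes_strict = (
        no_incompatible
        and not report.unclear_pairs
        and (not report.missing_pairs or not strict_missing)
    )
    if required_functions and strain_table:
        for fn in sorted(required_functions):
            covering = [
                m for m in consortium.members if fn in strain_table[m].functions
            ]
            report.function_coverage[fn] = sorted(covering)
            if not covering:
                report.uncovered_functions.append(fn)
    return report


def enumerate_consortia(
    strains: dict[str, Strain],
    matrix: CompatibilityMatrix,
    required_functions: set[str] | None = None,
    size_range: tuple[int, int] = (2, 10),
    policy: str = "lenient",
    selected_only: bool = True,
) -> list[Consortium]:
    """Enumerate candidate consortia as maximal cliques of the policy graph.

    Maximal cliques come from Bron-Kerbosch with pivoting (networkx
    ``find_cliques``); they are filtered to sizes within ``size_range`` and to
    cliques whose members jointly cover ``required_functions``.  Output order
    is deterministic: size descending, then lexicographic member list.
    Sub-consortia of a returned clique are derivable by the caller and are not
    expanded here.
    """
    lo, hi = size_range
    if lo < 2:
        raise ValueError("minimum consortium size is 2")
    required = set(required_functions or ())
    pool = {
        name: s for name, s in strains.items() if s.selected or not selected_only
    }
    for fn in required:
        if not any(fn in s.functions for s in pool.values()):
            warnings.warn(
                f"required function {fn!r} is possessed by no strain in the pool; "
                "no consortium can cover it",
                stacklevel=2,
            )
            return []
    graph = build_graph(matrix, policy=policy, strains=set(pool))
    results = []
    for clique in nx.find_cliques(graph):
        if not lo <= len(clique) <= hi:
            continue
        covered = set().union(*(pool[m].functions for m in clique))
        if not required <= covered:
            continue
        results.append(Consortium(name="", members=tuple(sorted(clique)), policy=policy))
    results.sort(key=lambda c: (-len(c.members), c.members))
    return [
        Consortium(name=f"C{i:03d}", members=c.members, policy=policy)
        for i, c in enumerate(results, start=1)
    ]
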