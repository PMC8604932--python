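"""Regulation-matrix set algebra and Fisher's exact enrichment tests.

Downstream-target sets shared by a group of regulators (e.g. an ohnolog
pair such as STP1/STP2) are intersected from the regulation matrix, and the
enrichment of change-gene sets (mean change or noise-only change) in those
shared targets is assessed with Fisher's exact test over the tested-gene
universe.  Change genes are also labelled Known/Novel against the
regulation matrix to separate recovered interactions from new candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import GeneSet, RegulationMatrix

__all__ = [
    "ContingencyTable",
    "InteractionCall",
    "shared_downstream",
    "fisher_enrichment",
    "call_interactions",
    "redundancy_candidates",
]


@dataclass
class ContingencyTable:
    """2x2 table over the tested-gene universe.

    ``a``: change genes inside the target set, ``b``: change genes outside,
    ``c``: non-change genes inside, ``d``: non-change genes outside.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class InteractionCall:
    """One detected regulator->target interaction.

    ``status`` is Known when the edge is present in the (evidence-filtered)
    regulation matrix and Novel otherwise; ``basis`` records which change
    signature detected it.
    """

    regulator: str
    target: str
    status: str  # Known | Novel
    basis: str   # MeanChange | NoiseOnly | NoiseChange


def shared_downstream(rm: RegulationMatrix, group) -> GeneSet:
    """Intersection of the target sets of all regulators in ``group``.

    A regulator absent from the matrix contributes an empty target set
    (making the result empty) and triggers a warning.
    """
    group = list(group)
    if not group:
        raise ValueError("regulator group must be non-empty")
    known = rm.regulators()
    targets: set[str] | None = None
    for reg in group:
        if reg not in known:
            warnings.warn(f"regulator {reg!r} absent from regulation matrix", stacklevel=2)
            return GeneSet(f"shared:{'+'.join(group)}", set())
        t = rm.targets_of(reg)
        targets = t if targets is None else targets & t
    return GeneSet(f"shared:{'+'.join(group)}", targets or set())


def fisher_enrichment(
    changes: GeneSet,
    target: GeneSet,
    universe: GeneSet,
    alternative: str = "greater",
) -> tuple[float, ContingencyTable]:
    """Fisher's exact test for enrichment of ``changes`` in ``target``.

    ``target`` is intersected with the universe before tabulation (genes
    not expressed in the compared strains are excluded).  ``alternative``
    is ``"greater"`` (one-sided enrichment, the default) or
    ``"two-sided"``.  A degenerate table (any margin zero) returns p = 1
    with a warning.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    uni = universe.members
    if not changes.members <= uni:
        raise ValueError("changes must be a subset of the universe")
    tgt = target.members & uni
    chg = changes.members
    a = len(chg & tgt)
    b = len(chg - tgt)
    c = len(tgt - chg)
    d = len(uni - tgt - chg)
    table = ContingencyTable(a, b, c, d)
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate contingency table (zero margin); p = 1", stacklevel=2)
        return 1.0, table
    p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1]
    return float(p), table


def call_interactions(
    deleted: str,
    changes: pd.DataFrame,
    rm: RegulationMatrix,
) -> list[InteractionCall]:
    """Interaction calls for every changed gene of a deletion comparison.

    ``changes`` is a called differential table.  Each gene whose call is
    neither NoChange nor Excluded yields one call with the deleted
    regulator; additionally, genes with significant noise regardless of
    mean (``noise_significant``) are listed under basis ``NoiseChange``,
    matching the wider candidate definition used for novel-target listings.
    """
    known_edges = rm.edge_set
    calls: list[InteractionCall] = []
    for gene, row in changes.iterrows():
        bases = []
        if row["call"] in ("MeanChange", "NoiseOnly"):
            bases.append(row["call"])
        if bool(row.get("noise_significant", False)) and row["call"] != "NoiseOnly":
            bases.append("NoiseChange")
        for basis in bases:
            status = "Known" if (deleted, gene) in known_edges else "Novel"
            calls.append(InteractionCall(deleted, str(gene), status, basis))
    return calls


def redundancy_candidates(tables: dict[str, pd.DataFrame]) -> GeneSet:
    """Genes called NoiseOnly in *every* deletion strain of a redundant pair.

    A redundantly regulated target should show noise-only change in each
    single-deletion strain of its compensating pair.
    """
    sets = [
        set(dt.index[dt["call"] == "NoiseOnly"]) for dt in tables.values()
    ]
    common = set.intersection(*sets) if sets else set()
    return GeneSet("noise_only_in_all_deletions", common)


def interaction_table(calls: list[InteractionCall]) -> pd.DataFrame:
    """Edge-list table (regulator, target, status, basis) for reports."""
    return pd.DataFrame(
        [(c.regulator, c.target, c.status, c.basis) for c in calls],
        columns=["regulator", "target", "status", "basis"],
    )
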