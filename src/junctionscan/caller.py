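"""Turn fragment-level support into fusion calls with whitelist rescue.

The general rule requires ``min_support`` supporting fragments (default 2)
before a fusion is reported.  Events below that threshold are *discarded* —
the fate of the one-read KIAA1549:BRAF fusions under the unoptimized
workflow — unless the gene pair is on a curated known-fusion whitelist, in
which case a single supporting fragment suffices and the call is flagged
``rescued``.  Junctions with no support at all are *absent*.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .junction_reference import Junction, KnownFusionList
from .scanner import FragmentSupport

STATUS_REPORTED = "reported"
STATUS_DISCARDED = "discarded"
STATUS_ABSENT = "absent"


@dataclass(frozen=True)
class CallerParams:
    """min_support: fragments required for a non-whitelisted fusion.
    variant_strict: require the exon variant itself to be whitelisted, not
    just the gene pair."""

    whitelist: KnownFusionList
    min_support: int = 2
    variant_strict: bool = False

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass(frozen=True)
class FusionCall:
    junction_id: str
    gene5: str
    gene3: str
    exon5: int
    exon3: int
    support: int
    whitelisted: bool
    rescued: bool
    status: str
    primary: bool


def decide_status(support: int, whitelisted: bool, min_support: int) -> tuple[str, bool]:
    """Closed-form (status, rescued) assignment for one junction."""
    if support == 0:
        return STATUS_ABSENT, False
    if support >= min_support:
        return STATUS_REPORTED, False
    if whitelisted:
        return STATUS_REPORTED, True
    return STATUS_DISCARDED, False


def call_fusions(
    junctions: Sequence[Junction],
    supports: Iterable[FragmentSupport] | Mapping[str, int],
    params: CallerParams,
) -> list[FusionCall]:
    """One call per junction variant, each decided independently.

    ``supports`` may omit junctions (treated as zero support) but must not
    reference junctions without metadata.  Within each gene pair the variant
    with the highest support is marked ``primary`` (ties broken by the lower
    5' exon rank); pairs with no support have no primary variant.  Rows are
    ordered by (gene pair, exon5, exon3).
    """
    if isinstance(supports, Mapping):
        support_by_id = dict(supports)
    else:
        support_by_id = {s.junction_id: s.support for s in supports}
    known_ids = {j.junction_id for j in junctions}
    orphans = set(support_by_id) - known_ids
    if orphans:
        raise ValueError(f"support without junction gene metadata: {sorted(orphans)}")

    ordered = sorted(junctions, key=lambda j: (j.gene5, j.gene3, j.exon5, j.exon3))
    calls: list[FusionCall] = []
    for j in ordered:
        support = int(support_by_id.get(j.junction_id, 0))
        whitelisted = params.whitelist.matches(
            j.gene5, j.gene3, j.exon5, j.exon3, strict=params.variant_strict
        )
        status, rescued = decide_status(support, whitelisted, params.min_support)
        calls.append(
            FusionCall(
                junction_id=j.junction_id,
                gene5=j.gene5,
                gene3=j.gene3,
                exon5=j.exon5,
                exon3=j.exon3,
                support=support,
                whitelisted=whitelisted,
                rescued=rescued,
                status=status,
                primary=False,
            )
        )

    # mark the best-supported variant per gene pair
    by_pair: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(calls):
        by_pair.setdefault((c.gene5, c.gene3), []).append(i)
    for indices in by_pair.values():
        with_support = [i for i in indices if calls[i].support > 0]
        if not with_support:
            continue
        best = min(with_support, key=lambda i: (-calls[i].support, calls[i].exon5))
        c = calls[best]
        calls[best] = FusionCall(**{**asdict(c), "primary": True})
    return calls


_CALL_COLUMNS = [
    "gene1",
    "gene2",
    "exon1",
    "exon2",
    "split_reads",
    "whitelisted",
    "rescued",
    "status",
    "primary",
]


def write_calls(calls: Sequence[FusionCall], path: str | Path) -> None:
    """Fusion calls TSV (gene1/gene2 follow common fusion-caller column
    naming; split_reads is the fragment-level support count)."""
    rows = [
        {
            "gene1": c.gene5,
            "gene2": c.gene3,
            "exon1": c.exon5,
            "exon2": c.exon3,
            "split_reads": c.support,
            "whitelisted": c.whitelisted,
            "rescued": c.rescued,
            "status": c.status,
            "primary": c.primary,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[FusionCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for row in df.to_dict("records"):
        exon5 = int(row["exon1"])
        exon3 = int(row["exon2"])
        calls.append(
            FusionCall(
                junction_id=f"{row['gene1']}:{row['gene2']}|e{exon5}:e{exon3}",
                gene5=str(row["gene1"]),
                gene3=str(row["gene2"]),
                exon5=exon5,
                exon3=exon3,
                support=int(row["split_reads"]),
                whitelisted=bool(row["whitelisted"]),
                rescued=bool(row["rescued"]),
                status=str(row["status"]),
                primary=bool(row["primary"]),
            )
        )
    return calls
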