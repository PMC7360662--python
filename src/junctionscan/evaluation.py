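"""Sample-level detection outcomes and cohort summaries.

The per-sample taxonomy follows the reported / discarded / missed scheme used
to describe KIAA1549:BRAF detectability: a fusion-positive sample is
*reported* when any exon variant of the target pair is called, *discarded*
when evidence was found but filtered out (below-threshold support without
rescue), and *missed* when no evidence was found at all ("absent" is the
call-level name for the same zero-support state).  Fusion-negative samples
are *true_negative* or *false_positive*; any evidence at all — reported or
discarded — counts against specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .caller import FusionCall, read_calls

POSITIVE_STATUSES = ("reported", "discarded", "missed")
NEGATIVE_STATUSES = ("true_negative", "false_positive")
ALL_STATUSES = POSITIVE_STATUSES + NEGATIVE_STATUSES


@dataclass(frozen=True)
class SampleOutcome:
    sample_id: str
    truth_positive: bool
    status: str

    def __post_init__(self) -> None:
        expected = POSITIVE_STATUSES if self.truth_positive else NEGATIVE_STATUSES
        if self.status not in expected:
            raise ValueError(
                f"status {self.status!r} invalid for truth_positive={self.truth_positive}"
            )


def evaluate_sample(
    calls: Sequence[FusionCall],
    truth_positive: bool,
    target_pair: tuple[str, str],
    sample_id: str = "sample",
) -> SampleOutcome:
    """Classify one sample from its calls for the target gene pair."""
    gene5, gene3 = target_pair
    target = [c for c in calls if c.gene5 == gene5 and c.gene3 == gene3]
    if not target:
        raise ValueError(
            f"target pair {gene5}:{gene3} absent from the scanned junction set"
        )
    statuses = {c.status for c in target}
    if truth_positive:
        if "reported" in statuses:
            status = "reported"
        elif "discarded" in statuses:
            status = "discarded"
        else:
            status = "missed"
    else:
        status = (
            "false_positive" if statuses & {"reported", "discarded"} else "true_negative"
        )
    return SampleOutcome(sample_id=sample_id, truth_positive=truth_positive, status=status)


@dataclass
class CohortSummary:
    """Counts and relative frequencies per status, stratified by truth.

    Frequencies are percentages within each truth stratum and are reported
    to one decimal place; raw counts are always carried alongside.
    ``detected`` merges reported + discarded among positives (both the merged
    and unmerged views are reported because both are used in practice).
    """

    counts: dict[str, int]
    n_positive: int
    n_negative: int

    @property
    def sensitivity(self) -> Optional[float]:
        if self.n_positive == 0:
            return None
        return self.counts["reported"] / self.n_positive

    @property
    def specificity(self) -> Optional[float]:
        if self.n_negative == 0:
            return None
        return self.counts["true_negative"] / self.n_negative

    @property
    def detected_fraction(self) -> Optional[float]:
        if self.n_positive == 0:
            return None
        return (self.counts["reported"] + self.counts["discarded"]) / self.n_positive

    def frequencies(self) -> dict[str, float]:
        """Exact (unrounded) percentages within each truth stratum."""
        freqs: dict[str, float] = {}
        for status in POSITIVE_STATUSES:
            if self.n_positive:
                freqs[status] = 100.0 * self.counts[status] / self.n_positive
        for status in NEGATIVE_STATUSES:
            if self.n_negative:
                freqs[status] = 100.0 * self.counts[status] / self.n_negative
        return freqs

    def to_dict(self) -> dict:
        d = {
            "counts": dict(self.counts),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "frequencies_pct": {k: round(v, 1) for k, v in self.frequencies().items()},
        }
        if self.sensitivity is not None:
            d["sensitivity"] = self.sensitivity
            d["detected_fraction"] = self.detected_fraction
        if self.specificity is not None:
            d["specificity"] = self.specificity
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def summarize_cohort(outcomes: Sequence[SampleOutcome]) -> CohortSummary:
    if not outcomes:
        raise ValueError("cannot summarize an empty cohort")
    counts = {status: 0 for status in ALL_STATUSES}
    for o in outcomes:
        counts[o.status] += 1
    n_positive = sum(1 for o in outcomes if o.truth_positive)
    return CohortSummary(
        counts=counts, n_positive=n_positive, n_negative=len(outcomes) - n_positive
    )


def compare_cohorts(
    summary_a: CohortSummary,
    summary_b: CohortSummary,
    labels: tuple[str, str] = ("cohort_a", "cohort_b"),
) -> pd.DataFrame:
    """Status x cohort contingency table of absolute counts, suitable for a
    chi-square or Fisher test in any statistics environment (the test itself
    is left to the user)."""
    return pd.DataFrame(
        {
            labels[0]: [summary_a.counts[s] for s in ALL_STATUSES],
            labels[1]: [summary_b.counts[s] for s in ALL_STATUSES],
        },
        index=list(ALL_STATUSES),
    )


def write_outcomes(outcomes: Sequence[SampleOutcome], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": o.sample_id,
                "truth_positive": o.truth_positive,
                "status": o.status,
            }
            for o in outcomes
        ]
    ).to_csv(path, sep="\t", index=False)


def evaluate_manifest(
    manifest_path: str | Path, target_pair: tuple[str, str]
) -> list[SampleOutcome]:
    """Evaluate a cohort manifest TSV with columns sample_id, truth_positive
    and calls_path (paths resolved relative to the manifest)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    outcomes = []
    for row in df.to_dict("records"):
        calls_path = Path(str(row["calls_path"]))
        if not calls_path.is_absolute():
            calls_path = manifest_path.parent / calls_path
        outcomes.append(
            evaluate_sample(
                read_calls(calls_path),
                truth_positive=bool(row["truth_positive"]),
                target_pair=target_pair,
                sample_id=str(row["sample_id"]),
            )
        )
    return outcomes
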