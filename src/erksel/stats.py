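"""dAUC difference statistic, per-segment ranking, and panel classification.

For one peptide segment, ``dAUC = sum_t (uptake_apo - uptake_inhibitor)_t``
over the labelling time points, computed on in-exchange-corrected uptake.
Large positive dAUC means strong protection by the inhibitor.  Inhibitors
are ranked per segment (rank 1 = most protected) and classified on two
conformation-reporting segments (DFG motif 161-168 and P+1 191-198 by
default) with a scale-free rule: per-segment min-max normalization of
dAUC across the panel, averaging the two normalized scores, and fixed
thresholds on the combined score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from erksel.models import ConformationalClass
from erksel.uptake import UptakeCurve, curves_from_table

__all__ = [
    "DAUCRecord",
    "ClassificationResult",
    "DegenerateNormalizationWarning",
    "compute_dauc",
    "dauc_table",
    "rank_inhibitors",
    "classify_panel",
    "DEFAULT_SEGMENTS",
    "DEFAULT_THRESHOLDS",
]

#: Default conformation-reporting segments used for classification.
DEFAULT_SEGMENTS = ("DFG_161-168", "P+1_191-198")
#: (t_low, t_high) thresholds on the combined normalized score.
DEFAULT_THRESHOLDS = (0.4, 0.6)


class DegenerateNormalizationWarning(UserWarning):
    """All dAUC values identical in a segment: normalization is undefined."""


@dataclass
class DAUCRecord:
    inhibitor_id: str
    segment_id: str
    dauc: float
    rank: float | None = None


@dataclass
class ClassificationResult:
    inhibitor_id: str
    normalized_scores: dict[str, float]
    combined_score: float = field(init=False)
    label: ConformationalClass = field(init=False)

    def finalize(self, t_low: float, t_high: float) -> "ClassificationResult":
        self.combined_score = float(np.mean(list(self.normalized_scores.values())))
        if self.combined_score >= t_high:
            self.label = ConformationalClass.R_SELECTIVE
        elif self.combined_score <= t_low:
            self.label = ConformationalClass.EXCHANGE
        else:
            self.label = ConformationalClass.INTERMEDIATE
        return self


def compute_dauc(apo: UptakeCurve, inhibitor: UptakeCurve) -> float:
    """Sum over time points of (apo - inhibitor) corrected uptake (Da).

    Antisymmetric under argument swap; requires identical peptides and
    time grids.
    """
    if (apo.peptide.start, apo.peptide.end) != (
        inhibitor.peptide.start,
        inhibitor.peptide.end,
    ):
        raise ValueError("dAUC requires matching peptides")
    if apo.times.shape != inhibitor.times.shape or not np.allclose(
        apo.times, inhibitor.times
    ):
        raise ValueError("dAUC requires identical time grids")
    return float(np.sum(apo.corrected_uptake - inhibitor.corrected_uptake))


def dauc_table(
    df: pd.DataFrame,
    protein_state: str = "2P",
    segments: tuple[str, ...] | None = None,
    peptides: list | None = None,
) -> list[DAUCRecord]:
    """Compute dAUC for every (inhibitor, segment) in an uptake table.

    ``segments`` filters by segment id (``name_start-end``); by default
    every peptide present is used.  Apo curves come from the ``apo``
    condition of the same protein state.  ``peptides`` supplies named
    peptide definitions for segment ids; the generator's default map is
    used when omitted.
    """
    if peptides is None:
        from erksel.synthetic import default_peptides

        peptides = default_peptides()
    pep_map = {(p.start, p.end): p for p in peptides}
    apo_curves = curves_from_table(df, protein_state, "apo", pep_map)
    conditions = [
        c for c in df["condition"].unique() if c != "apo"
    ]
    records: list[DAUCRecord] = []
    for condition in conditions:
        curves = curves_from_table(df, protein_state, condition, pep_map)
        for key, curve in curves.items():
            seg = curve.peptide.segment_id
            if segments is not None and seg not in segments:
                continue
            records.append(
                DAUCRecord(
                    inhibitor_id=condition,
                    segment_id=seg,
                    dauc=compute_dauc(apo_curves[key], curve),
                )
            )
    return records


def rank_inhibitors(records: list[DAUCRecord], segment_id: str) -> list[DAUCRecord]:
    """Fill ranks for one segment: descending dAUC -> ascending rank.

    Rank 1 is the most protected inhibitor; ties get the average rank.
    """
    seg = [r for r in records if r.segment_id == segment_id]
    if not seg:
        raise ValueError(f"no records for segment {segment_id!r}")
    ranks = rankdata([-r.dauc for r in seg], method="average")
    for rec, rank in zip(seg, ranks):
        rec.rank = float(rank)
    return seg


def classify_panel(
    records: list[DAUCRecord],
    segments: tuple[str, str] = DEFAULT_SEGMENTS,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> list[ClassificationResult]:
    """Classify every inhibitor from its dAUC on two segments.

    Per-segment min-max normalization to [0, 1] across the full record
    set (reference compounds spanning the dynamic range should be
    included), then the combined score is the mean of the two normalized
    scores and thresholds assign R_SELECTIVE (>= t_high), EXCHANGE
    (<= t_low), or INTERMEDIATE.
    """
    t_low, t_high = thresholds
    by_seg: dict[str, dict[str, float]] = {}
    for seg in segments:
        vals = {r.inhibitor_id: r.dauc for r in records if r.segment_id == seg}
        if not vals:
            raise ValueError(f"segment {seg!r} absent from records")
        by_seg[seg] = vals
    inhibitors = set.intersection(*(set(v) for v in by_seg.values()))
    missing = set.union(*(set(v) for v in by_seg.values())) - inhibitors
    if missing:
        raise ValueError(f"inhibitors missing a segment: {sorted(missing)}")

    normalized: dict[str, dict[str, float]] = {i: {} for i in inhibitors}
    for seg, vals in by_seg.items():
        arr = np.array([vals[i] for i in inhibitors])
        lo, hi = float(arr.min()), float(arr.max())
        if np.isclose(hi, lo):
            warnings.warn(
                f"segment {seg!r}: degenerate normalization (max == min)",
                DegenerateNormalizationWarning,
                stacklevel=2,
            )
            for i in inhibitors:
                normalized[i][seg] = 0.5
        else:
            for i in inhibitors:
                normalized[i][seg] = (vals[i] - lo) / (hi - lo)

    return [
        ClassificationResult(inhibitor_id=i, normalized_scores=normalized[i]).finalize(
            t_low, t_high
        )
        for i in sorted(inhibitors)
    ]
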