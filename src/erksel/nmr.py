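"""Slow-exchange NMR analysis: R:L populations, CSPs, probe categories.

In the slow-exchange regime (Delta-omega >> k_ex) each conformer gives a
separate resonance whose volume is proportional to its population, so
``p_R = V_R / (V_R + V_L)`` read directly from a peak pair.  Chemical
shift perturbations combine the 1H and 13C dimensions as
``sqrt(ddH^2 + (w * ddC)^2)`` with a methyl carbon weight w (default
0.25).  Probes are categorized from the pattern of CSPs and broadening
across an inhibitor panel with known class labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pointbiserialr

from erksel.models import ConformationalClass, LeftSideGroup, ProbeCategory

__all__ = [
    "BROADENED",
    "BroadenedPairError",
    "PeakPair",
    "PopulationEstimate",
    "CSPRecord",
    "pair_peaks",
    "estimate_populations",
    "chemical_shift_perturbation",
    "csp_matrix",
    "categorize_probes",
    "write_csp_matrix",
    "read_csp_matrix",
]

#: Sentinel for a peak lost to exchange broadening in a CSP matrix.
BROADENED = "BROADENED"

#: A peak counts as broadened when its volume falls below this fraction of
#: the probe's apoenzyme volume.
DETECTION_FRACTION = 0.05

DEFAULT_CARBON_WEIGHT = 0.25


class BroadenedPairError(ValueError):
    """Population estimation requested for a broadened peak pair."""


@dataclass(frozen=True)
class PeakPair:
    """R- and L-state 2D peaks of one methyl probe."""

    probe_id: str
    h_ppm_R: float
    c_ppm_R: float
    volume_R: float
    h_ppm_L: float
    c_ppm_L: float
    volume_L: float
    broadened: bool = False


@dataclass(frozen=True)
class PopulationEstimate:
    probe_id: str
    p_R: float
    uncertainty: float = 0.0

    @property
    def p_L(self) -> float:
        return 1.0 - self.p_R


@dataclass(frozen=True)
class CSPRecord:
    probe_id: str
    inhibitor_id: str
    delta_delta: float
    carbon_weight: float = DEFAULT_CARBON_WEIGHT


def pair_peaks(
    peak_table: pd.DataFrame,
    apo_volumes: dict[str, float] | None = None,
    detection_fraction: float = DETECTION_FRACTION,
) -> dict[str, PeakPair]:
    """Build :class:`PeakPair` objects from a peak-table CSV (R/L rows).

    Only probes with both an R and an L row (exchange reporters) yield a
    pair.  A pair is flagged broadened when both volumes fall below
    ``detection_fraction`` of the probe's apo total volume (default: of
    its own total).
    """
    pairs: dict[str, PeakPair] = {}
    for probe_id, grp in peak_table.groupby("probe_id"):
        states = set(grp["state"])
        if not {"R", "L"} <= states:
            continue
        r = grp[grp["state"] == "R"].iloc[0]
        l = grp[grp["state"] == "L"].iloc[0]
        ref = (
            apo_volumes.get(probe_id, 1.0) if apo_volumes is not None else
            max(float(r["volume"]) + float(l["volume"]), 0.0) or 1.0
        )
        broadened = (
            float(r["volume"]) < detection_fraction * ref
            and float(l["volume"]) < detection_fraction * ref
        )
        pairs[probe_id] = PeakPair(
            probe_id=probe_id,
            h_ppm_R=float(r["h_ppm"]), c_ppm_R=float(r["c_ppm"]),
            volume_R=float(r["volume"]),
            h_ppm_L=float(l["h_ppm"]), c_ppm_L=float(l["c_ppm"]),
            volume_L=float(l["volume"]),
            broadened=broadened,
        )
    return pairs


def estimate_populations(
    pair: PeakPair,
    volume_noise_sd: float | None = None,
    detection_fraction: float = DETECTION_FRACTION,
) -> PopulationEstimate:
    """Volume-ratio population estimate ``p_R = V_R / (V_R + V_L)``.

    Volumes below ``detection_fraction`` of the larger peak are treated
    as undetected (zero), which also guards the estimate against small
    negative noise excursions.  When ``volume_noise_sd`` is given the
    uncertainty is first-order error propagation of independent volume
    noise through the ratio.
    """
    if pair.broadened:
        raise BroadenedPairError(
            f"{pair.probe_id}: both peaks broadened; no population estimate"
        )
    v_r, v_l = max(pair.volume_R, 0.0), max(pair.volume_L, 0.0)
    floor = detection_fraction * max(v_r, v_l)
    v_r = 0.0 if v_r < floor else v_r
    v_l = 0.0 if v_l < floor else v_l
    total = v_r + v_l
    if total <= 0:
        raise ValueError(f"{pair.probe_id}: both volumes zero")
    p_r = v_r / total
    uncertainty = 0.0
    if volume_noise_sd is not None:
        uncertainty = (
            volume_noise_sd * math.hypot(v_l, v_r) / total**2
        )
    return PopulationEstimate(probe_id=pair.probe_id, p_R=p_r, uncertainty=uncertainty)


def chemical_shift_perturbation(
    apo: tuple[float, float],
    bound: tuple[float, float],
    carbon_weight: float = DEFAULT_CARBON_WEIGHT,
) -> float:
    """Combined 1H/13C CSP: ``sqrt(ddH^2 + (w * ddC)^2)`` in ppm."""
    if carbon_weight <= 0:
        raise ValueError("carbon_weight must be > 0")
    dd_h = bound[0] - apo[0]
    dd_c = bound[1] - apo[1]
    return math.hypot(dd_h, carbon_weight * dd_c)


def csp_matrix(
    apo_table: pd.DataFrame,
    bound_tables: dict[str, pd.DataFrame],
    carbon_weight: float = DEFAULT_CARBON_WEIGHT,
    detection_fraction: float = DETECTION_FRACTION,
) -> pd.DataFrame:
    """CSP matrix (probes x inhibitors) with the BROADENED sentinel.

    Single-peak (``obs``) probes contribute a CSP from their position
    change; probes whose bound peak drops below the detection fraction
    of the apo volume are marked BROADENED for that inhibitor.  Exchange
    reporters (R/L rows) are excluded: their positions report conformer
    identity, not perturbation.
    """
    apo_obs = apo_table[apo_table["state"] == "obs"].set_index("probe_id")
    cols = {}
    for inhibitor_id, table in bound_tables.items():
        obs = table[table["state"] == "obs"].set_index("probe_id")
        col = {}
        for probe_id, apo_row in apo_obs.iterrows():
            if probe_id not in obs.index:
                continue
            row = obs.loc[probe_id]
            if float(row["volume"]) < detection_fraction * float(apo_row["volume"]):
                col[probe_id] = BROADENED
            else:
                col[probe_id] = chemical_shift_perturbation(
                    (float(apo_row["h_ppm"]), float(apo_row["c_ppm"])),
                    (float(row["h_ppm"]), float(row["c_ppm"])),
                    carbon_weight,
                )
        cols[inhibitor_id] = col
    return pd.DataFrame(cols)


#: Minimum point-biserial correlation for reporter classification and the
#: minimum CSP dynamic range (ppm) below which a probe is considered flat.
CORRELATION_THRESHOLD = 0.8
MIN_DYNAMIC_RANGE = 0.02


def categorize_probes(
    matrix: pd.DataFrame,
    class_labels: dict[str, ConformationalClass],
    left_side_groups: dict[str, LeftSideGroup] | None = None,
    correlation_threshold: float = CORRELATION_THRESHOLD,
    min_dynamic_range: float = MIN_DYNAMIC_RANGE,
) -> dict[str, ProbeCategory]:
    """Categorize probes from a CSP matrix and panel metadata.

    CONTACT_BROADENED: broadened under every inhibitor.  R_STATE_REPORTER:
    point-biserial correlation of CSP with the R-selective indicator
    exceeds the threshold.  LEFT_SIDE_REPORTER: analogous for the
    tetrahydropyran left-side indicator.  Probes with a flat CSP profile
    (dynamic range below ``min_dynamic_range``) or insufficient data are
    UNCLASSIFIED.
    """
    inhibitors = [c for c in matrix.columns if c in class_labels]
    if len(inhibitors) < len(matrix.columns):
        missing = sorted(set(matrix.columns) - set(inhibitors))
        raise ValueError(f"inhibitors without class labels: {missing}")
    n_rsel = sum(
        class_labels[i] is ConformationalClass.R_SELECTIVE for i in inhibitors
    )
    if n_rsel < 2 or len(inhibitors) - n_rsel < 2:
        raise ValueError("need >= 2 inhibitors per class for correlation")

    out: dict[str, ProbeCategory] = {}
    for probe_id, row in matrix.iterrows():
        values = row[inhibitors]
        is_broad = values == BROADENED
        if is_broad.all():
            out[probe_id] = ProbeCategory.CONTACT_BROADENED
            continue
        ok = [i for i in inhibitors if values[i] != BROADENED and pd.notna(values[i])]
        csps = np.array([float(values[i]) for i in ok])
        if len(ok) < 4 or csps.max() - csps.min() < min_dynamic_range:
            out[probe_id] = ProbeCategory.UNCLASSIFIED
            continue
        r_indicator = np.array(
            [class_labels[i] is ConformationalClass.R_SELECTIVE for i in ok], float
        )
        category = ProbeCategory.UNCLASSIFIED
        if len(set(r_indicator)) == 2:
            r_corr = pointbiserialr(r_indicator, csps).statistic
            if r_corr >= correlation_threshold:
                category = ProbeCategory.R_STATE_REPORTER
        if category is ProbeCategory.UNCLASSIFIED and left_side_groups is not None:
            left_indicator = np.array(
                [
                    left_side_groups.get(i) is LeftSideGroup.TETRAHYDROPYRAN
                    for i in ok
                ],
                float,
            )
            if len(set(left_indicator)) == 2:
                l_corr = pointbiserialr(left_indicator, csps).statistic
                if l_corr >= correlation_threshold:
                    category = ProbeCategory.LEFT_SIDE_REPORTER
        out[probe_id] = category
    return out


def write_csp_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index_label="probe_id")


def read_csp_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="probe_id")
    return df.apply(
        lambda col: col.map(lambda v: v if v == BROADENED else float(v))
    )
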