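"""Deuterium-uptake computation and corrected time-course assembly.

The measurement chain mirrors standard bottom-up HDX-MS processing: the
intensity-weighted average (centroid) mass of each peptide's isotope
distribution is referenced to its unlabelled form to give uptake in Da,
and the uptake recorded for the in-exchange control (quenched with no
labelling incubation) is subtracted from every time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from erksel.models import PeptideDef

PROTON_MASS = 1.007276

__all__ = [
    "NegativeUptakeWarning",
    "SpectrumEnvelope",
    "UptakeCurve",
    "centroid_mass",
    "deuterium_uptake",
    "in_exchange_correct",
    "build_time_course",
    "write_uptake_csv",
    "read_uptake_csv",
    "curves_from_table",
]


class NegativeUptakeWarning(UserWarning):
    """Raised when a (corrected) uptake value is negative.

    Negative values are preserved, not clamped: clamping would bias the
    downstream dAUC statistic toward protection.
    """


@dataclass(frozen=True)
class SpectrumEnvelope:
    """An isotope distribution for one peptide charge state."""

    mz_values: np.ndarray
    intensities: np.ndarray
    charge: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz_values", np.asarray(self.mz_values, float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, float))
        if self.mz_values.shape != self.intensities.shape:
            raise ValueError("mz_values and intensities must have equal length")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


def centroid_mass(envelope: SpectrumEnvelope) -> float:
    """Intensity-weighted average neutral mass (Da) of an envelope.

    m/z values are de-charged with the proton mass so that the result is
    independent of charge state.
    """
    total = envelope.intensities.sum()
    if total <= 0:
        raise ValueError("envelope has no intensity")
    mean_mz = float(np.dot(envelope.mz_values, envelope.intensities) / total)
    return mean_mz * envelope.charge - envelope.charge * PROTON_MASS


def deuterium_uptake(deuterated_centroid: float, undeuterated_centroid: float) -> float:
    """Uptake in Da: labelled centroid referenced to the unlabelled form.

    Negative differences are returned as-is with a warning.
    """
    diff = deuterated_centroid - undeuterated_centroid
    if diff < 0:
        warnings.warn(
            f"negative uptake ({diff:.3f} Da)", NegativeUptakeWarning, stacklevel=2
        )
    return diff


@dataclass
class UptakeCurve:
    """Per-peptide uptake vs labelling time with in-exchange correction."""

    peptide: PeptideDef
    times: np.ndarray
    raw_uptake: np.ndarray
    in_exchange: float = 0.0
    corrected_uptake: np.ndarray = field(default=None)  # type: ignore[assignment]
    uptake_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.raw_uptake = np.asarray(self.raw_uptake, float)
        if self.times.shape != self.raw_uptake.shape:
            raise ValueError("times and raw_uptake must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.corrected_uptake is None:
            self.corrected_uptake = self.raw_uptake - self.in_exchange
        else:
            self.corrected_uptake = np.asarray(self.corrected_uptake, float)


def in_exchange_correct(curve: UptakeCurve, control_uptake: float) -> UptakeCurve:
    """Subtract the in-exchange control from every time point.

    Returns a new curve; the raw values are retained.  Corrected values
    that fall below zero are preserved with a warning.
    """
    if control_uptake < 0:
        raise ValueError("control_uptake must be >= 0")
    corrected = curve.raw_uptake - control_uptake
    if np.any(corrected < 0):
        warnings.warn(
            "in-exchange correction produced negative uptake",
            NegativeUptakeWarning,
            stacklevel=2,
        )
    return UptakeCurve(
        peptide=curve.peptide,
        times=curve.times,
        raw_uptake=curve.raw_uptake,
        in_exchange=control_uptake,
        corrected_uptake=corrected,
        uptake_sd=curve.uptake_sd,
    )


def build_time_course(
    replicates: list[tuple[float, float]], peptide: PeptideDef | None = None
) -> UptakeCurve:
    """Assemble a time course from (time_s, uptake_Da) replicate pairs.

    Replicates at the same time are averaged; per-time standard deviation
    is recorded (0 for singletons).
    """
    if not replicates:
        raise ValueError("no replicates provided")
    df = pd.DataFrame(replicates, columns=["time_s", "uptake_Da"])
    grouped = df.groupby("time_s")["uptake_Da"].agg(["mean", "std", "count"])
    grouped["std"] = grouped["std"].fillna(0.0)
    if peptide is None:
        peptide = PeptideDef(start=1, end=2, sequence="AA")
    return UptakeCurve(
        peptide=peptide,
        times=grouped.index.to_numpy(float),
        raw_uptake=grouped["mean"].to_numpy(),
        in_exchange=0.0,
        uptake_sd=grouped["std"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# CSV dialect shared with the synthetic generator

_UPTAKE_COLUMNS = [
    "protein_state",
    "condition",
    "peptide_start",
    "peptide_end",
    "sequence",
    "time_s",
    "uptake_Da",
    "replicate",
    "is_in_exchange",
]


def write_uptake_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_UPTAKE_COLUMNS, float_format="%.6f")


def read_uptake_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_UPTAKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"uptake table missing columns: {sorted(missing)}")
    df["is_in_exchange"] = df["is_in_exchange"].astype(bool)
    return df


def curves_from_table(
    df: pd.DataFrame,
    protein_state: str,
    condition: str,
    peptides: dict[tuple[int, int], PeptideDef] | None = None,
) -> dict[tuple[int, int], UptakeCurve]:
    """Extract corrected per-peptide curves for one (state, condition).

    Replicates are averaged after in-exchange correction; the two
    operations commute because the control is a per-peptide constant.
    In-exchange rows are identified by their flag (time_s = 0 sentinel).
    """
    sel = df[(df["protein_state"] == protein_state) & (df["condition"] == condition)]
    if sel.empty:
        raise ValueError(f"no rows for state={protein_state!r}, condition={condition!r}")
    out: dict[tuple[int, int], UptakeCurve] = {}
    for (start, end, seq), grp in sel.groupby(
        ["peptide_start", "peptide_end", "sequence"]
    ):
        key = (int(start), int(end))
        peptide = peptides.get(key) if peptides is not None else None
        if peptide is None:
            peptide = PeptideDef(start=int(start), end=int(end), sequence=str(seq))
        control_rows = grp[grp["is_in_exchange"]]
        # a noisy control can read below zero; only non-negative deuterium
        # content is subtractable
        control = (
            max(float(control_rows["uptake_Da"].mean()), 0.0)
            if len(control_rows)
            else 0.0
        )
        label_rows = grp[~grp["is_in_exchange"]]
        agg = label_rows.groupby("time_s")["uptake_Da"].agg(["mean", "std"])
        agg["std"] = agg["std"].fillna(0.0)
        raw = UptakeCurve(
            peptide=peptide,
            times=agg.index.to_numpy(float),
            raw_uptake=agg["mean"].to_numpy(),
            uptake_sd=agg["std"].to_numpy(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NegativeUptakeWarning)
            out[key] = in_exchange_correct(raw, control)
    return out
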