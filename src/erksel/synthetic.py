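"""Synthetic HDX-MS and slow-exchange NMR data generator.

Forward model
-------------
Every dataset derives from the two-state ensemble R<->L.  Because the
conformational exchange rate (k_ex ~ 300 1/s) vastly exceeds every
observable amide exchange rate on the labelling grid (slowest time point
30 s), each residue exchanges at the population-weighted mean rate

    k_obs = p_R * k_int / PF_R  +  p_L * k_int / PF_L

(the fast-ensemble limit), where PF_R and PF_L are the per-state
protection factors.  Peptide-level uptake is the sum of independent
single-exponential site contributions scaled by the labelling fraction
(default 0.9, i.e. 90% D2O) and a constant back-exchange survival factor
(default 0.75 for the simulated LC setup).

Inhibitors act through two knobs: a population shift (``bound_p_R``) and
region-specific protection multipliers — steric multipliers on ligand
contact regions, and an "allosteric" multiplier on the DFG/beta9, P+1
and helix-alphaF segments of the 2P form only, modelling the long-range
rigidification that accompanies R-state trapping.  Unphosphorylated (0P)
datasets keep p_R = 0 throughout: the R state is a feature of the
activated kinase.

Default study conditions
------------------------
The default panel holds 17 development compounds plus BVD523 and ATG017,
with VTX11e and GDC0994 as the R-selective and exchange-retaining
reference points, and ground-truth classes of 13 R-selective /
3 exchange-retaining / 1 intermediate among the panel compounds.  The
nine-point labelling grid spans 0.5-180 min.  Segment sequences other
than the three documented peptides (161-168 LKICDFGL, 191-198 YRAPEIML,
203-210 YTKSIDIW) are synthetic placeholders of the correct length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from scipy import stats as _sstats

from erksel.intrinsic import intrinsic_rates
from erksel.models import (
    APO_2P_25C,
    ConformationalClass,
    ConformerModel,
    InhibitorClassSpec,
    LeftSideGroup,
    MethylProbeSpec,
    PeptideDef,
    ProbeCategory,
    Region,
    ResidueExchangeSpec,
    Scaffold,
)
from erksel.uptake import PROTON_MASS, SpectrumEnvelope, UptakeCurve

__all__ = [
    "TIME_GRID_S",
    "DEUTERIUM_INCREMENT",
    "default_peptides",
    "default_panel",
    "default_probes",
    "panel_compound_ids",
    "build_residue_specs",
    "simulate_peptide_uptake",
    "simulate_in_exchange",
    "simulate_isotope_envelope",
    "simulate_panel",
    "simulate_hmqc_peak_pairs",
    "write_peak_csv",
    "read_peak_csv",
]

#: Labelling time grid in seconds: 0.5, 1, 3, 8, 16, 30, 60, 90, 180 min.
TIME_GRID_S = tuple(60.0 * m for m in (0.5, 1, 3, 8, 16, 30, 60, 90, 180))

#: Mass difference between deuterium and protium, Da.
DEUTERIUM_INCREMENT = 1.006277

#: Natural 13C abundance used for the envelope's natural-isotope binomial.
_P_13C = 0.0107

LABELING_FRACTION = 0.9
BACK_EXCHANGE_FACTOR = 0.75

#: Quench-handling window (s) and rate slowdown used for the in-exchange
#: control: deuterium acquired while samples sit in quench conditions.
QUENCH_WINDOW_S = 30.0
QUENCH_SLOWDOWN = 100.0

# Baseline per-state protection factors by region class.  In regions that
# report conformation selection the R state is the more protected one
# (PF_R > PF_L); ligand contact regions are equally protected in R and L.
_BASELINE_PF: dict[Region, tuple[float, float]] = {
    # (PF_R, PF_L)
    Region.ALLOSTERIC: (300.0, 30.0),
    Region.CONTACT: (50.0, 50.0),
    Region.CONTACT_2P: (50.0, 50.0),
    Region.OTHER: (50.0, 50.0),
}


def default_peptides() -> list[PeptideDef]:
    """The default peptide map covering contact and allosteric segments."""
    return [
        PeptideDef(28, 37, "SYIGEGAYGM", Region.CONTACT, name="GlyLoop"),
        PeptideDef(60, 68, "QYIVQDLME", Region.CONTACT, name="alphaC"),
        PeptideDef(103, 110, "QHLSNDHI", Region.CONTACT, name="hinge"),
        PeptideDef(135, 142, "EHQKLTDE", Region.CONTACT, name="alphaE"),
        PeptideDef(151, 158, "NVLKTTCD", Region.CONTACT_2P, name="beta7-beta8"),
        PeptideDef(161, 168, "LKICDFGL", Region.ALLOSTERIC, name="DFG"),
        PeptideDef(191, 198, "YRAPEIML", Region.ALLOSTERIC, name="P+1"),
        PeptideDef(203, 210, "YTKSIDIW", Region.ALLOSTERIC, name="alphaF"),
        PeptideDef(341, 348, "MELIFQET", Region.CONTACT, name="alphaL16"),
    ]


def panel_compound_ids() -> list[str]:
    """The 17 development-panel compound ids."""
    return [f"#{i}" for i in range(1, 18)]


_R_SELECTIVE_PANEL = {"#2", "#3", "#5", "#6", "#7", "#8", "#9", "#10", "#11", "#12",
                      "#14", "#16", "#17"}
_EXCHANGE_PANEL = {"#4", "#13", "#15"}
_THP_LEFT = {"#4", "#6", "#8", "#15"}


def default_panel(
    apo: ConformerModel = APO_2P_25C, include_references: bool = True
) -> list[InhibitorClassSpec]:
    """Ground-truth inhibitor panel: 17 compounds + BVD523 + ATG017.

    VTX11e and GDC0994 are appended as the reference points used for
    dAUC normalization when ``include_references`` is true.
    """

    def _spec(iid: str, cls: ConformationalClass, **kw) -> InhibitorClassSpec:
        if cls is ConformationalClass.R_SELECTIVE:
            kw.setdefault("bound_p_R", 1.0)
            kw.setdefault("allosteric_protection_multiplier", 20.0)
        elif cls is ConformationalClass.EXCHANGE:
            kw.setdefault("bound_p_R", apo.p_R)
            kw.setdefault("allosteric_protection_multiplier", 1.0)
        else:
            kw.setdefault("bound_p_R", 0.9)
            kw.setdefault("allosteric_protection_multiplier", 5.0)
        return InhibitorClassSpec(
            inhibitor_id=iid, conformational_class=cls,
            contact_protection_multiplier=20.0, **kw,
        )

    panel: list[InhibitorClassSpec] = []
    for iid in panel_compound_ids():
        if iid in _R_SELECTIVE_PANEL:
            cls = ConformationalClass.R_SELECTIVE
        elif iid in _EXCHANGE_PANEL:
            cls = ConformationalClass.EXCHANGE
        else:
            cls = ConformationalClass.INTERMEDIATE
        left = (
            LeftSideGroup.TETRAHYDROPYRAN
            if iid in _THP_LEFT
            else LeftSideGroup.PYRAZOLE
        )
        scaffold = (
            Scaffold.PYRIDONE if iid in _EXCHANGE_PANEL else Scaffold.TRIAZOLOPYRAZINE
        )
        panel.append(_spec(iid, cls, left_side_group=left, scaffold=scaffold))
    panel.append(
        _spec("BVD523", ConformationalClass.R_SELECTIVE,
              left_side_group=LeftSideGroup.OTHER, scaffold=Scaffold.AMIDOPYRROLE)
    )
    panel.append(
        _spec("ATG017", ConformationalClass.EXCHANGE,
              left_side_group=LeftSideGroup.OTHER, scaffold=Scaffold.OTHER)
    )
    if include_references:
        panel.append(
            _spec("VTX11e", ConformationalClass.R_SELECTIVE,
                  left_side_group=LeftSideGroup.OTHER, scaffold=Scaffold.AMIDOPYRROLE)
        )
        panel.append(
            _spec("GDC0994", ConformationalClass.EXCHANGE,
                  left_side_group=LeftSideGroup.PYRAZOLE, scaffold=Scaffold.PYRIDONE)
        )
    return panel


# ---------------------------------------------------------------------------
# HDX forward model


def build_residue_specs(
    peptide: PeptideDef,
    pD: float = 7.0,
    temperature_C: float = 25.0,
    baseline_pf: tuple[float, float] | None = None,
) -> list[ResidueExchangeSpec]:
    """Per-residue exchange specs for a peptide with region-baseline PFs."""
    pf_r, pf_l = baseline_pf or _BASELINE_PF[peptide.region]
    rates = intrinsic_rates(peptide.sequence, pD=pD, temperature_C=temperature_C)
    specs: list[ResidueExchangeSpec] = []
    for offset, aa in enumerate(peptide.sequence):
        if offset == 0:
            continue
        is_pro = aa == "P"
        specs.append(
            ResidueExchangeSpec(
                residue_index=peptide.start + offset,
                amino_acid=aa,
                intrinsic_rate=0.0 if is_pro else float(rates[offset]),
                protection_factor_L=pf_l,
                protection_factor_R=pf_r,
                is_proline=is_pro,
            )
        )
    return specs


def _protection_multiplier(
    inhibitor: InhibitorClassSpec | None, region: Region, protein_state: str
) -> float:
    if inhibitor is None:
        return 1.0
    if region is Region.CONTACT:
        return inhibitor.contact_protection_multiplier
    if region is Region.CONTACT_2P and protein_state == "2P":
        return inhibitor.contact_protection_multiplier
    if region is Region.ALLOSTERIC and protein_state == "2P":
        return inhibitor.allosteric_protection_multiplier
    return 1.0


def _observed_rates(
    residues: list[ResidueExchangeSpec],
    model: ConformerModel,
    inhibitor: InhibitorClassSpec | None,
    region: Region,
    protein_state: str,
) -> np.ndarray:
    """Population-weighted per-residue observed rates (fast-ensemble limit)."""
    if protein_state == "0P":
        p_r = 0.0  # the R state exists only in the activated kinase
    elif inhibitor is not None:
        p_r = inhibitor.bound_p_R
    else:
        p_r = model.p_R
    mult = _protection_multiplier(inhibitor, region, protein_state)
    k = []
    for res in residues:
        if res.is_proline:
            continue
        k.append(
            p_r * res.intrinsic_rate / (mult * res.protection_factor_R)
            + (1.0 - p_r) * res.intrinsic_rate / (mult * res.protection_factor_L)
        )
    return np.asarray(k)


def simulate_peptide_uptake(
    peptide: PeptideDef,
    residues: list[ResidueExchangeSpec],
    model: ConformerModel,
    inhibitor: InhibitorClassSpec | None = None,
    times=TIME_GRID_S,
    labeling_fraction: float = LABELING_FRACTION,
    back_exchange_factor: float = BACK_EXCHANGE_FACTOR,
    protein_state: str = "2P",
) -> UptakeCurve:
    """Noise-free peptide uptake time course under the two-state model.

    ``uptake(t) = f_label * f_backex * sum_i (1 - exp(-k_obs_i * t))``
    over the peptide's exchangeable amides; non-decreasing in t and
    bounded by ``f_label * f_backex * n_exchangeable``.
    """
    times = np.asarray(times, float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be sorted strictly ascending")
    if not 0.0 < labeling_fraction <= 1.0:
        raise ValueError("labeling_fraction must be in (0, 1]")
    k_obs = _observed_rates(residues, model, inhibitor, peptide.region, protein_state)
    uptake = (
        labeling_fraction
        * back_exchange_factor
        * (1.0 - np.exp(-np.outer(times, k_obs))).sum(axis=1)
    )
    return UptakeCurve(peptide=peptide, times=times, raw_uptake=uptake)


def simulate_in_exchange(
    peptide: PeptideDef,
    residues: list[ResidueExchangeSpec],
    model: ConformerModel,
    inhibitor: InhibitorClassSpec | None = None,
    labeling_fraction: float = LABELING_FRACTION,
    back_exchange_factor: float = BACK_EXCHANGE_FACTOR,
    protein_state: str = "2P",
) -> float:
    """Deuterium (Da) accrued during quench handling (the in-exchange control).

    Modelled as exchange for a fixed window at a strongly reduced
    effective rate, yielding a small constant per-peptide offset.
    """
    k_obs = _observed_rates(residues, model, inhibitor, peptide.region, protein_state)
    t_eff = QUENCH_WINDOW_S / QUENCH_SLOWDOWN
    return float(
        labeling_fraction
        * back_exchange_factor
        * (1.0 - np.exp(-k_obs * t_eff)).sum()
    )


# ---------------------------------------------------------------------------
# Isotope envelopes


def simulate_isotope_envelope(
    peptide: PeptideDef, deuteration_probability: float, charge: int = 2
) -> SpectrumEnvelope:
    """Isotope envelope: natural-abundance binomial convolved with the
    deuteration binomial over the peptide's exchangeable amides.

    All peaks sit on a grid spaced by the H->D mass increment (1.006277
    Da) divided by charge; the small difference from the 13C spacing is
    a deliberate single-increment simplification that leaves centroid
    arithmetic exact.
    """
    if not 0.0 <= deuteration_probability <= 1.0:
        raise ValueError("deuteration_probability must be in [0, 1]")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    m0 = _pmass.calculate_mass(sequence=peptide.sequence, monoisotopic=True)
    n_c = _pmass.Composition(sequence=peptide.sequence)["C"]
    nat = _sstats.binom.pmf(np.arange(n_c + 1), n_c, _P_13C)
    n_ex = peptide.n_exchangeable
    deut = _sstats.binom.pmf(np.arange(n_ex + 1), n_ex, deuteration_probability)
    intensities = np.convolve(nat, deut)
    keep = intensities > 1e-12
    idx = np.arange(intensities.size)
    masses = m0 + idx * DEUTERIUM_INCREMENT
    mz = (masses + charge * PROTON_MASS) / charge
    intensities = intensities / intensities.sum()
    return SpectrumEnvelope(mz_values=mz[keep], intensities=intensities[keep],
                            charge=charge)


# ---------------------------------------------------------------------------
# Panel simulation


def simulate_panel(
    panel: list[InhibitorClassSpec] | None = None,
    peptides: list[PeptideDef] | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    times=TIME_GRID_S,
    apo_2p: ConformerModel = APO_2P_25C,
    labeling_fraction: float = LABELING_FRACTION,
    back_exchange_factor: float = BACK_EXCHANGE_FACTOR,
) -> pd.DataFrame:
    """Full HDX dataset: 0P and 2P forms, apo + every inhibitor, all
    peptides, the full time grid, plus an in-exchange control row per
    condition (time_s = 0 sentinel, ``is_in_exchange`` flag).

    With ``noise_sd = 0`` the output is deterministic and seed-independent;
    with noise the same seed reproduces the dataset bit-identically.
    Saturating binding is assumed throughout.
    """
    panel = default_panel(apo=apo_2p) if panel is None else panel
    peptides = default_peptides() if peptides is None else peptides
    ids = [inh.inhibitor_id for inh in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate inhibitor_id in panel")
    for inh in panel:
        inh.validate_against_apo(apo_2p)

    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    residue_cache = {
        p.segment_id: build_residue_specs(p, temperature_C=apo_2p.temperature_C)
        for p in peptides
    }
    apo_0p = ConformerModel(p_R=0.0, k_ex=apo_2p.k_ex,
                            temperature_C=apo_2p.temperature_C)

    rows: list[dict] = []
    for protein_state, model in (("0P", apo_0p), ("2P", apo_2p)):
        for condition, inhibitor in [("apo", None)] + [(i.inhibitor_id, i) for i in panel]:
            for pep in peptides:
                residues = residue_cache[pep.segment_id]
                curve = simulate_peptide_uptake(
                    pep, residues, model, inhibitor, times,
                    labeling_fraction, back_exchange_factor, protein_state,
                )
                ie = simulate_in_exchange(
                    pep, residues, model, inhibitor,
                    labeling_fraction, back_exchange_factor, protein_state,
                )
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, noise_sd) if rng is not None else 0.0
                    rows.append(
                        _row(protein_state, condition, pep, 0.0, ie + noise, rep, True)
                    )
                    for t, u in zip(curve.times, curve.raw_uptake):
                        noise = rng.normal(0.0, noise_sd) if rng is not None else 0.0
                        # measured uptake includes handling deuterium
                        rows.append(
                            _row(protein_state, condition, pep, t,
                                 u + ie + noise, rep, False)
                        )
    return pd.DataFrame(rows)


def _row(state, condition, pep, t, uptake, rep, is_ie) -> dict:
    return {
        "protein_state": state,
        "condition": condition,
        "peptide_start": pep.start,
        "peptide_end": pep.end,
        "sequence": pep.sequence,
        "time_s": t,
        "uptake_Da": uptake,
        "replicate": rep,
        "is_in_exchange": is_ie,
    }


# ---------------------------------------------------------------------------
# NMR peak simulation


def default_probes(k_ex: float = 300.0) -> list[MethylProbeSpec]:
    """Default ILV methyl probe set with ground-truth categories."""

    def single(pid, h, c, cat):
        return MethylProbeSpec(pid, (h, c), (h, c), cat, k_ex=k_ex)

    return [
        MethylProbeSpec("I72", (0.62, 12.5), (1.05, 14.8),
                        ProbeCategory.EXCHANGE_REPORTER, k_ex=k_ex),
        MethylProbeSpec("L220", (0.85, 24.2), (0.45, 21.9),
                        ProbeCategory.EXCHANGE_REPORTER, k_ex=k_ex),
        MethylProbeSpec("L242", (0.30, 22.0), (0.78, 24.6),
                        ProbeCategory.EXCHANGE_REPORTER, k_ex=k_ex),
        single("I196", 0.71, 13.2, ProbeCategory.R_STATE_REPORTER),
        single("I345", 0.55, 11.0, ProbeCategory.R_STATE_REPORTER),
        single("L26", 0.88, 23.1, ProbeCategory.LEFT_SIDE_REPORTER),
        single("L105", 0.67, 24.9, ProbeCategory.LEFT_SIDE_REPORTER),
        single("L155", 0.92, 22.4, ProbeCategory.LEFT_SIDE_REPORTER),
        single("L161", 0.40, 25.3, ProbeCategory.LEFT_SIDE_REPORTER),
        single("I82", 0.77, 12.9, ProbeCategory.CONTACT_BROADENED),
        single("L154", 0.81, 23.7, ProbeCategory.CONTACT_BROADENED),
        single("V12", 0.83, 21.2,
               ProbeCategory.CONTACT_BROADENED_EXCEPT_AMIDOPYRROLE),
        single("V37", 0.95, 20.6,
               ProbeCategory.CONTACT_BROADENED_EXCEPT_AMIDOPYRROLE),
        single("I101", 0.69, 13.8,
               ProbeCategory.CONTACT_BROADENED_EXCEPT_AMIDOPYRROLE),
    ]


#: Peak-position displacement (1H ppm) of a fully R-shifted complex at an
#: R-state reporter, and of a tetrahydropyran left side at a left-side
#: reporter; exchange-retaining / non-THP complexes show the residual value.
_R_REPORTER_CSP = 0.12
_LEFT_THP_CSP = 0.10
_LEFT_OTHER_CSP = 0.02
_AMIDOPYRROLE_SURVIVOR_CSP = 0.03


def _csp_shift(
    probe: MethylProbeSpec,
    model: ConformerModel,
    inhibitor: InhibitorClassSpec | None,
) -> float:
    if inhibitor is None:
        return 0.0
    if probe.category is ProbeCategory.R_STATE_REPORTER:
        if model.p_R >= 1.0:
            return 0.0
        response = (inhibitor.bound_p_R - model.p_R) / (1.0 - model.p_R)
        return _R_REPORTER_CSP * response
    if probe.category is ProbeCategory.LEFT_SIDE_REPORTER:
        if inhibitor.left_side_group is LeftSideGroup.TETRAHYDROPYRAN:
            return _LEFT_THP_CSP
        return _LEFT_OTHER_CSP
    if probe.category is ProbeCategory.CONTACT_BROADENED_EXCEPT_AMIDOPYRROLE:
        return _AMIDOPYRROLE_SURVIVOR_CSP
    return 0.0


def _is_broadened(
    probe: MethylProbeSpec, inhibitor: InhibitorClassSpec | None
) -> bool:
    if inhibitor is None:
        return False
    if probe.category is ProbeCategory.CONTACT_BROADENED:
        return True
    if probe.category is ProbeCategory.CONTACT_BROADENED_EXCEPT_AMIDOPYRROLE:
        return inhibitor.scaffold is not Scaffold.AMIDOPYRROLE
    return False


def simulate_hmqc_peak_pairs(
    probes: list[MethylProbeSpec] | None = None,
    model: ConformerModel = APO_2P_25C,
    inhibitor: InhibitorClassSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated 2D methyl peak table (probe_id, state, h_ppm, c_ppm, volume).

    Exchange reporters emit an R and an L peak with volumes proportional
    to the conformer populations (total 1 per probe before noise); other
    probes emit a single peak (state ``obs``) whose position carries the
    inhibitor's chemical-shift perturbation.  Broadened probes emit zero
    volume under the applicable inhibitors.  Gaussian noise (sd as a
    fraction of total probe volume) is added to volumes only.
    """
    probes = default_probes(k_ex=model.k_ex) if probes is None else probes
    rng = np.random.default_rng(seed) if noise_sd > 0 else None

    rows: list[dict] = []
    for probe in probes:
        if probe.category is ProbeCategory.EXCHANGE_REPORTER:
            p = inhibitor.bound_p_R if inhibitor is not None else model.p_R
            for state, (h, c), vol in (
                ("R", probe.shift_R, p),
                ("L", probe.shift_L, 1.0 - p),
            ):
                if rng is not None:
                    vol = vol + rng.normal(0.0, noise_sd)
                rows.append(
                    {"probe_id": probe.probe_id, "state": state,
                     "h_ppm": h, "c_ppm": c, "volume": vol}
                )
        else:
            vol = 0.0 if _is_broadened(probe, inhibitor) else 1.0
            if rng is not None and vol > 0:
                vol = vol + rng.normal(0.0, noise_sd)
            h = probe.shift_R[0] + _csp_shift(probe, model, inhibitor)
            rows.append(
                {"probe_id": probe.probe_id, "state": "obs",
                 "h_ppm": h, "c_ppm": probe.shift_R[1], "volume": vol}
            )
    return pd.DataFrame(rows)


def write_peak_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False,
              columns=["probe_id", "state", "h_ppm", "c_ppm", "volume"])


def read_peak_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"probe_id", "state", "h_ppm", "c_ppm", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df
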