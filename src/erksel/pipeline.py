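"""End-to-end orchestration: simulate -> uptake -> dAUC -> classify -> NMR.

A :class:`RunConfig` (loadable from YAML) fixes every parameter and the
single seed from which all randomness flows; a run writes the
intermediate CSVs, a summary report, and a provenance block containing
the seed and a hash of the full parameter set, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from erksel.models import APO_2P_25C, APO_2P_5C, APO_0P, ConformerModel
from erksel.nmr import (
    BroadenedPairError,
    categorize_probes,
    csp_matrix,
    estimate_populations,
    pair_peaks,
    write_csp_matrix,
)
from erksel.stats import (
    DEFAULT_SEGMENTS,
    DEFAULT_THRESHOLDS,
    classify_panel,
    dauc_table,
    rank_inhibitors,
)
from erksel.synthetic import (
    default_panel,
    default_peptides,
    default_probes,
    simulate_hmqc_peak_pairs,
    simulate_panel,
    write_peak_csv,
)
from erksel.uptake import write_uptake_csv

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 0
    noise_sd: float = 0.0
    volume_noise_sd: float = 0.0
    n_replicates: int = 1
    apo_p_R: float = 0.8
    k_ex: float = 300.0
    temperature_C: float = 25.0
    segments: tuple[str, str] = DEFAULT_SEGMENTS
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    output_dir: str = "erksel_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "segments" in raw:
            raw["segments"] = tuple(raw["segments"])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)

    def parameter_hash(self) -> str:
        params = asdict(self)
        params.pop("output_dir")  # where outputs land is not a parameter
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report dict and writes CSVs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    apo = ConformerModel(
        p_R=config.apo_p_R, k_ex=config.k_ex, temperature_C=config.temperature_C
    )
    panel = default_panel(apo=apo)
    peptides = default_peptides()
    known_segments = {p.segment_id for p in peptides}
    unknown = set(config.segments) - known_segments
    if unknown:
        raise ValueError(f"unknown segment id(s): {sorted(unknown)}")

    # HDX branch
    uptake_df = simulate_panel(
        panel, peptides, seed=config.seed, noise_sd=config.noise_sd,
        n_replicates=config.n_replicates, apo_2p=apo,
    )
    write_uptake_csv(uptake_df, outdir / "uptake.csv")
    records = dauc_table(uptake_df, protein_state="2P")
    for seg in sorted({r.segment_id for r in records}):
        rank_inhibitors(records, seg)
    dauc_df = pd.DataFrame(
        [
            {"inhibitor_id": r.inhibitor_id, "segment_id": r.segment_id,
             "dauc": r.dauc, "rank": r.rank}
            for r in records
        ]
    )
    dauc_df.to_csv(outdir / "dauc.csv", index=False, float_format="%.6f")
    results = classify_panel(records, config.segments, config.thresholds)
    cls_df = pd.DataFrame(
        [
            {
                "inhibitor_id": r.inhibitor_id,
                **{f"score_{s}": v for s, v in r.normalized_scores.items()},
                "combined_score": r.combined_score,
                "label": r.label.value,
            }
            for r in results
        ]
    )
    cls_df.to_csv(outdir / "classification.csv", index=False, float_format="%.6f")

    # NMR branch
    probes = default_probes(k_ex=config.k_ex)
    seed_seq = np.random.SeedSequence(config.seed)
    nmr_seeds = [int(s) % 2**31 for s in seed_seq.generate_state(len(panel) + 3)]
    apo_models = {"2P_25C": APO_2P_25C, "2P_5C": APO_2P_5C, "0P": APO_0P}
    pop_rows = []
    apo_tables = {}
    for (label, model), seed in zip(apo_models.items(), nmr_seeds):
        table = simulate_hmqc_peak_pairs(
            probes, model, None, config.volume_noise_sd, seed
        )
        apo_tables[label] = table
        for probe_id, pair in pair_peaks(table).items():
            try:
                est = estimate_populations(
                    pair, config.volume_noise_sd or None
                )
            except (BroadenedPairError, ValueError):
                continue
            pop_rows.append(
                {"condition": f"apo_{label}", "probe_id": probe_id,
                 "p_R": est.p_R, "uncertainty": est.uncertainty}
            )
    bound_tables = {}
    for inhibitor, seed in zip(panel, nmr_seeds[3:]):
        table = simulate_hmqc_peak_pairs(
            probes, apo, inhibitor, config.volume_noise_sd, seed
        )
        bound_tables[inhibitor.inhibitor_id] = table
        for probe_id, pair in pair_peaks(table).items():
            try:
                est = estimate_populations(pair, config.volume_noise_sd or None)
            except (BroadenedPairError, ValueError):
                continue
            pop_rows.append(
                {"condition": inhibitor.inhibitor_id, "probe_id": probe_id,
                 "p_R": est.p_R, "uncertainty": est.uncertainty}
            )
    pop_df = pd.DataFrame(pop_rows)
    pop_df.to_csv(outdir / "populations.csv", index=False, float_format="%.6f")
    write_peak_csv(apo_tables["2P_25C"], outdir / "peaks_apo_2P_25C.csv")

    matrix = csp_matrix(apo_tables["2P_25C"], bound_tables)
    write_csp_matrix(matrix, outdir / "csp_matrix.csv")
    categories = categorize_probes(
        matrix,
        {i.inhibitor_id: i.conformational_class for i in panel},
        {i.inhibitor_id: i.left_side_group for i in panel},
    )
    cat_df = pd.DataFrame(
        [{"probe_id": p, "category": c.value} for p, c in sorted(categories.items())]
    )
    cat_df.to_csv(outdir / "probe_categories.csv", index=False)

    report = {
        "classification": cls_df.to_dict(orient="records"),
        "n_r_selective": int((cls_df["label"] == "R_SELECTIVE").sum()),
        "populations": pop_df.to_dict(orient="records"),
        "probe_categories": {p: c.value for p, c in categories.items()},
        "provenance": {
            "seed": config.seed,
            "parameter_hash": config.parameter_hash(),
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
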