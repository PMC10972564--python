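# erksel

Conformation-selection analysis for ATP-competitive ERK2 inhibitors.

Active, dual-phosphorylated ERK2 (2P-ERK2) exchanges between two global
conformers, L and R, at k_ex ≈ 300 s⁻¹; the R state supports productive
ATP binding and exists only in the activated kinase.  Some ATP-competitive
inhibitors trap the R state (conformation selection), others bind without
perturbing the L↔R equilibrium.  The distinction matters for drug design
because R-state trapping propagates allosterically to the activation loop
and the substrate-docking interface.

`erksel` is a toolkit for the two solution readouts of this behaviour and
their structural correlates, aimed at researchers analysing peptide-level
HDX-MS and methyl-NMR data on two-state kinases:

- **HDX-MS**: per-peptide deuterium uptake D(t) with in-exchange
  correction, and the difference-area statistic
  **dAUC = Σ_t (D_apo − D_inhibitor)_t** over the nine-point labelling
  grid (0.5–180 min), used to rank inhibitors per segment and classify
  them as R-selective / exchange-retaining / intermediate from the DFG
  (161–168) and P+1 (191–198) segments.
- **Slow-exchange NMR**: for methyl probes with Δω ≫ k_ex, separate R and
  L peaks have population-proportional volumes, so
  **p_R = V_R / (V_R + V_L)**; combined chemical-shift perturbations
  Δδ = √(Δδ_H² + (0.25·Δδ_C)²) categorize probes as R-state reporters,
  left-side-chemistry reporters, or broadened contacts.
- **Structural geometry**: Kabsch superposition on the ERK2 C-terminal
  domain Cα set (109–141, 205–245, 272–310), per-residue RMSDs between
  phosphoforms, and halogen–π (ring-centroid) distances.
- **Synthetic data**: a fully seeded forward model of both experiments
  under the two-state ensemble, so every stage is testable without any
  download.  Amides exchange at the population-weighted rate
  k_obs = p_R·k_int/PF_R + p_L·k_int/PF_L (fast-ensemble limit), and a
  19-compound inhibitor panel (plus two reference compounds) carries
  class-dependent population shifts and region-specific protection.

See `docs/methods.md` for model details and assumptions.

## Worked example

Simulate the default noiseless panel, compute dAUC on the
conformation-reporting segments, and classify:

```python
from erksel.synthetic import simulate_panel
from erksel.stats import dauc_table, classify_panel, rank_inhibitors

df = simulate_panel(noise_sd=0.0)           # 0P/2P, apo + 21 conditions
records = dauc_table(df)                    # per (inhibitor, segment)
rank_inhibitors(records, "DFG_161-168")
for r in records:
    if r.segment_id == "DFG_161-168" and r.inhibitor_id in ("#8", "#15", "#1"):
        print(f"{r.inhibitor_id:4s} dAUC={r.dauc:6.3f} rank={r.rank}")
for c in classify_panel(records):
    if c.inhibitor_id in ("#8", "#15", "#1"):
        print(c.inhibitor_id, round(c.combined_score, 3), c.label.value)
```

```
#1   dAUC= 8.455 rank=16.0
#8   dAUC=20.759 rank=8.0
#15  dAUC= 0.000 rank=19.0
#1 0.415 INTERMEDIATE
#15 0.0 EXCHANGE
#8 1.0 R_SELECTIVE
```

Compound #8 protects the DFG segment by ~20.8 Da·timepoints relative to
apoenzyme — indistinguishable from the R-selective reference VTX11e — and
scores 1.0 after min–max normalization; #15 shows no protection beyond
the steric contact regions (score 0, exchange-retaining); #1 sits between
the clusters (0.415, intermediate).  Across the default panel this yields
13 R-selective / 3 exchange / 1 intermediate among the 17 development
compounds, and 14 R-selective among all 19 surveyed inhibitors.

Population estimation from a slow-exchange peak pair:

```python
from erksel.models import APO_2P_25C
from erksel.synthetic import simulate_hmqc_peak_pairs
from erksel.nmr import pair_peaks, estimate_populations

table = simulate_hmqc_peak_pairs(model=APO_2P_25C)     # R:L = 80:20
for pair in pair_peaks(table).values():
    print(pair.probe_id, estimate_populations(pair).p_R)
```

```
I72 0.8
L220 0.8
L242 0.8
```

The same stages are scriptable from the shell via the `erksel` command
(`simulate`, `dauc`, `classify`, `nmr`, `structure`, `run`); `erksel run`
executes the whole chain into an output directory with a provenance block
(seed + parameter hash) for reproducibility.

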