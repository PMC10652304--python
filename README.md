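# redoxsens

Oxidation-sensitivity scoring of joint proteomes.

Oxidative stress leaves covalent marks — advanced glycation and lipoxidation
end products (AGEs/ALEs), carbonylation, mono-/di-oxidation — on the
proteins of aging tissue such as osteoarthritic cartilage. Which of those
marks matter most? `redoxsens` implements an analytic chain that nominates
the proteins whose oxidative modification is predicted to perturb the
proteome the most, by integrating three signals:

1. **PTM change quantification.** From site-level MS evidence, the percent
   change in PTM per modified site between treated and vehicle conditions,

   %Δ PTM/site = 100 · (mean_treated − mean_vehicle) / mean_vehicle,

   averaged over a protein's sites, plus grand sums, sign censuses, LFQ
   overlays and Pearson/bootstrap correlation analyses.
2. **Network influence.** Eigenvector centrality *E* computed on the whole
   protein–protein interaction network (STRING-style edge list) and carried
   unchanged onto the subnetwork of detected proteins, so subnetwork values
   stay calibrated to the whole-proteome scale; Louvain communities of the
   subnetwork's largest connected component.
3. **Electrostatic destabilization.** A composition-only screened-Coulomb
   model of the folding free-energy change ΔΔG (kT) caused by adding or
   removing one charge. With native/denatured net charges
   Q_n = C⁺ + 0.4·C_His − C⁻ and Q_d = C⁺ + 0.1·C_His − C⁻ and Flory radii
   R_n = 2.24·N^0.392 Å, R_d = 1.927·N^0.598 Å,

   ΔΔG/kT = I_b(±2Q_d + 1) / (2R_d(1 + κR_d)) − I_b(±2Q_n + 1) / (2R_n(1 + κR_n)),

   with Bjerrum length I_b = 7.13 Å and inverse Debye length κ = 0.03 Å⁻¹.

These combine into the **composite sensitivity score**: the raw sensitivity
score RSS is the product of min–max-normalized |ΔΔG| and min–max-normalized
*E* over the scored set P, and CSS = minmax(RSS), so the top-ranked protein
scores exactly 1 and the bottom exactly 0.

A synthetic-data module generates proteomes with controlled charge
composition, scale-free networks with planted hubs, and PTM/LFQ evidence
with planted effects under count noise, so the whole chain is testable
against known ground truth.

## Worked example

Run the full pipeline on the bundled synthetic demo (2000-protein network,
500 detected proteins, 5 planted hubs):

```sh
redoxsens run-all --seed 1 --out demo_out
```

or from Python:

```python
from redoxsens.pipeline import PipelineConfig, run_all

cfg = PipelineConfig(out_dir="demo_out", seed=1, n_boot=500,
                     synthetic={"n_proteins_total": 2000, "n_detected": 500,
                                "network_model": "planted_hub", "n_planted_hubs": 5})
result = run_all(cfg)
print(result["summary_table"].head())
```

prints (abridged):

```
            community  old_sign  young_sign   css  css_exact
protein_id
P0000               5        -1           1  1.00   1.000000
P0008               6        -1          -1  0.31   0.312101
P0013               2        -1          -1  0.23   0.226672
P0002               9        -1          -1  0.18   0.178861
P0015               4         1          -1  0.15   0.147613
```

The top row is the protein combining the strongest destabilization
susceptibility with the highest network centrality; its CSS is exactly
1.00 by construction of the normalization chain. The report
(`demo_out/report.json`) summarizes the study-level quantities: in this run
the grand-sum PTM change is −13217 in the old treated arm versus +4780 in
the young arm (the generator's default study design plants predominantly
negative effects in old and positive in young), with an old-arm census of
482 decreasing / 18 increasing proteins, a 2000-node / 6152-edge network
whose 500-node detected subnetwork partitions at modularity 0.38, and the
planted hub `P0000` ranked first. Per-community CSS sums and the calibrated
centrality tables are written alongside as TSV.

Subcommands `simulate`, `ptm`, `network`, `stability` and `score` expose
the individual stages; `--config` accepts a YAML file mirroring
`PipelineConfig`.

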