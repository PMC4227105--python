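#!/usr/bin/env python
"""Generate the default synthetic study cohort and persist it.

Emulates the study design: a 40k-probe array manifest, 4 normal brain
samples, 20 paired early/late tumours (5 grade II->III, 5 II->IV, 10
III->IV), 70% IDH1-mutant pairs carrying a planted CIMP beta-shift, and
per-grade planted hypermethylated genes.  Small outputs (sample sheet,
ground truth, summary) go to results/cohort/; the full beta and detection
p-value matrices go to scratch/cohort/ (they are large and fully
reproducible from the seed).
"""

import argparse
import json
from pathlib import Path

from gliomethyl.model import write_manifest, write_matrix, write_sample_sheet
from gliomethyl.simulate import SimulationConfig, generate_cohort, generate_manifest

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    manifest = generate_manifest(cfg)
    beta, sheet, truth = generate_cohort(cfg, manifest)

    results = ROOT / "results" / "cohort"
    scratch = ROOT / "scratch" / "cohort"
    results.mkdir(parents=True, exist_ok=True)
    scratch.mkdir(parents=True, exist_ok=True)

    write_sample_sheet(sheet, results / "sample_sheet.csv")
    truth.to_json(results / "truth.json")
    write_manifest(manifest, scratch / "manifest.tsv")
    write_matrix(beta.beta, scratch / "beta.tsv")
    write_matrix(beta.detection_p, scratch / "detection_p.tsv")

    summary = {
        "seed": args.seed,
        "n_probes": int(len(beta.probe_ids)),
        "n_samples": int(len(beta.sample_ids)),
        "grade_group_sizes": {g: len(sheet.grade_group(g)) for g in ("II", "III", "IV")},
        "idh1_mutant_pairs": sheet.count_idh1_mut_pairs(),
        "cimp_positive_samples": len(truth.cimp_samples),
        "cimp_loci": len(truth.cimp_loci),
        "planted_genes_per_grade": {
            g: len(d) for g, d in truth.hyper_genes_by_grade.items()
        },
    }
    with open(results / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    print(f"cohort: {summary['n_samples']} samples x {summary['n_probes']} probes")
    print(f"grade groups II/III/IV: {list(summary['grade_group_sizes'].values())}")
    print(f"IDH1-mutant pairs: {summary['idh1_mutant_pairs']}/20; "
          f"CIMP+ samples: {summary['cimp_positive_samples']}")
    print(f"matrices under {scratch}, metadata under {results}")


if __name__ == "__main__":
    main()
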