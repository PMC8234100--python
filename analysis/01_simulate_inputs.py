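"""Generate every input the downstream stages consume.

Writes the toy annotation with its expected-event truth table, the 2-vs-2
RNA-seq count matrices with one planted splicing-index fold-change (-2.64
on the cassette exon), and the 24/72/32 three-group qPCR cohort with its
planted fold-changes, ratio shift, and covariate correlations.
"""

import argparse
import json
import os

import pandas as pd

from splicedex import synthetic_data as syn


def main(seed: int = 17, out_dir: str = "results/sim") -> None:
    os.makedirs(out_dir, exist_ok=True)
    spec = syn.SimulationSpec(seed=seed)

    models, truth = syn.make_toy_annotation(spec, os.path.join(out_dir, "annotation.gtf"))
    pd.DataFrame(truth, columns=["gene_id", "event_type", "feature_label"]).to_csv(
        os.path.join(out_dir, "truth_events.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "chrom_sizes.tsv"), "w") as fh:
        for c, s in syn.toy_chrom_sizes().items():
            fh.write(f"{c}\t{s}\n")

    exon_cm, const_cm, inter_cm, design, truth_counts = syn.simulate_counts(models, spec)
    exon_cm.to_tsv(os.path.join(out_dir, "exon_counts.tsv"))
    const_cm.to_tsv(os.path.join(out_dir, "constitutive_counts.tsv"))
    inter_cm.to_tsv(os.path.join(out_dir, "intergenic_counts.tsv"))
    pd.DataFrame(
        {"sample_id": list(design.groups), "group": list(design.groups.values())}
    ).to_csv(os.path.join(out_dir, "design.csv"), index=False)
    with open(os.path.join(out_dir, "truth_counts.json"), "w") as fh:
        json.dump(truth_counts, fh, indent=2)

    records, covariates, truth_cohort = syn.simulate_cohort(spec)
    syn.write_cohort(records, covariates, truth_cohort, out_dir)

    print(f"[01] {len(models)} toy genes, {len(truth)} expected events")
    print(f"[01] counts: {len(exon_cm.feature_ids)} exon/intron features, "
          f"{spec.counts.n_per_group} vs {spec.counts.n_per_group} samples")
    print(f"[01] cohort: {len(covariates)} subjects -> {out_dir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out-dir", default="results/sim")
    a = ap.parse_args()
    main(a.seed, a.out_dir)
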