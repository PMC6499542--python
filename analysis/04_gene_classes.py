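"""OFF-state noise, family over-representation, orthogonality, pan-neuronal genes.

Treats the generator's gene classes as gene families (the synthetic stand-in
for curated family annotations): measures each gene's OFF-state noise,
tests which families are over-represented among the top-FCR genes, scores
family orthogonality against a randomized null, and applies the seven-rule
pan-neuronal filter.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from celldiv.core import GeneFamilyCollection, population_means, to_fpkm
from celldiv.diffexp import build_dm, fit_group_model, pairwise_contrasts
from celldiv.diversity import diversity_scores, rank_top_fcr
from celldiv.gene_class import (
    enrichment,
    off_noise,
    orthogonality_z,
    pan_neuronal,
    select_noise_classes,
)
from celldiv.simulate import default_config, simulate_expression

SEED = 7
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    em, gt, truth = simulate_expression(default_config(seed=SEED))
    fp = to_fpkm(em, gt)
    cls = truth.gene_info["gene_class"]
    fams = GeneFamilyCollection(
        {name: frozenset(cls.index[cls == name]) for name in cls.unique()},
        source="generator classes",
    )

    # OFF-state noise
    noise = off_noise(fp)
    low, high = select_noise_classes(noise, min_max_expr=10.0)
    med = noise.join(cls).groupby("gene_class")["off_noise"].median()
    print("median OFF noise by class:")
    print(med.round(4).to_string())
    print(f"low-noise set: {len(low)} genes; high-noise set: {len(high)} genes")

    # enrichment of families among the top-FCR genes
    fit = fit_group_model(fp, max_replicates=2)
    de = pairwise_contrasts(fit)
    dm = build_dm(de)
    scores = diversity_scores(dm, np.abs(de.lfc))
    top = set(rank_top_fcr(scores, len(scores) // 10))
    enr = enrichment(top, set(scores.index), fams)
    print("family enrichment in the top FCR decile (hypergeometric):")
    print(enr[["overlap", "family_size", "p", "significant"]].to_string())

    # orthogonality vs randomized same-size families
    pm = population_means(fp, log_transform=True)
    orth_rows = []
    for name, members in fams.items():
        try:
            r = orthogonality_z(pm, members, n_draws=500, seed=SEED, family_name=name)
        except ValueError as e:
            print(f"orthogonality: {name}: {e}")
            continue
        orth_rows.append((name, r.family_size, r.observed, r.null_mean, r.z))
        print(f"orthogonality {name}: obs {r.observed:.3f} vs null "
              f"{r.null_mean:.3f} +- {r.null_std:.3f} (Z = {r.z:+.1f}, n = {r.family_size})")

    # pan-neuronal filter
    pm_lin = population_means(fp)
    pan = pan_neuronal(pm_lin)
    truth_pan = set(cls.index[cls == "pan_neuronal"])
    print(f"pan-neuronal filter: {len(pan)} genes pass; "
          f"{len(set(pan) & truth_pan)}/{len(truth_pan)} generated pan-neuronal recovered")

    RESULTS.mkdir(exist_ok=True)
    noise.join(cls).to_csv(RESULTS / "04_off_noise.tsv", sep="\t")
    enr.to_csv(RESULTS / "04_enrichment_top_fcr.tsv", sep="\t")
    pd.DataFrame(orth_rows, columns=["family", "n", "observed", "null_mean", "z"]).to_csv(
        RESULTS / "04_orthogonality.tsv", sep="\t", index=False
    )
    pd.Series(sorted(pan), name="gene").to_csv(RESULTS / "04_pan_neuronal.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
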