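#!/usr/bin/env python
"""Relate binding to knock-down effects, gene length, HAS and labels.

Reproduces the downstream comparisons on the synthetic study: knock-down
effect by binding bin (vs autosomes), bound long vs short genes at the
10 kb split, the length-effect correlation, mean distances to
high-affinity sites, and under-replication / housekeeping fractions.
"""

import os

import pandas as pd

from compscan.annotation import read_regions
from compscan.compare import (
    compare_bins,
    flag_fraction,
    has_distance_summary,
    has_distances,
    knockdown_effect,
    length_effect_correlation,
    length_split_comparison,
    overlap_fraction,
)
from compscan.config import load_config
from compscan.expression import filter_expressed
from compscan.simulate import simulate_study

OUT = "results/comparisons"


def main() -> None:
    cfg, _ = load_config(os.path.join(os.path.dirname(__file__), "study_config.yaml"))
    study = simulate_study(cfg["simulation"])
    ann = study.annotation
    calls = pd.read_csv("results/chip/binding_calls.tsv", sep="\t", index_col=0)
    comp = pd.read_csv("results/expression/compensation.tsv", sep="\t", index_col=0)

    expressed = filter_expressed(study.expression, ["male", "female"], 6.0)
    x_calls = calls[(calls["arm"] == "X") & calls.index.isin(expressed)]
    effects = knockdown_effect(study.expression, "knockdown", "control", 6.0)
    auto = effects[[g in expressed and ann[g].arm != "X" for g in effects.index]]

    os.makedirs(OUT, exist_ok=True)
    bins_df, cmps = compare_bins(effects, x_calls, auto)
    bins_df.to_csv(os.path.join(OUT, "effect_bins.tsv"), sep="\t", index=False)
    pd.DataFrame([c.summary() for c in cmps]).to_csv(
        os.path.join(OUT, "bin_comparisons.tsv"), sep="\t", index=False
    )
    print("knock-down effect by binding bin (median log2):")
    for _, r in bins_df.iterrows():
        print(f"  {r['bin']:>8}: {r['median']:+.3f} (n={r['n']})")

    ls = length_split_comparison(effects, x_calls, ann, cfg["length_threshold"])
    print(f"bound long vs short genes: medians "
          f"{ls.medians[0]:+.3f} vs {ls.medians[1]:+.3f}, p = {ls.p_value:.3g}")

    corr = length_effect_correlation(effects, x_calls, ann)
    print(f"length-effect Pearson R = {corr['r_bp']:.2f} (bp), "
          f"{corr['r_log10']:.2f} (log10), n = {corr['n']}")

    dists = has_distances(ann, study.has, genes=list(x_calls.index))
    hd = has_distance_summary(dists, x_calls, ann, cfg["length_threshold"])
    hd.to_csv(os.path.join(OUT, "has_distances.tsv"), sep="\t", index=False)
    means = {r["group"]: r["mean_distance"] for _, r in hd.iterrows()}
    print(f"mean distance to a high-affinity site: bound long "
          f"{means.get('bound_long', float('nan')) / 1000:.1f} kb, unbound long "
          f"{means.get('unbound_long', float('nan')) / 1000:.1f} kb")

    comp_x = set(comp.index[comp["compensated"]]) & set(x_calls.index)
    unbound_comp = [g for g in comp_x if not x_calls.loc[g, "bound"]]
    strong_comp = [g for g in comp_x if x_calls.loc[g, "value"] > 5]
    ur = study.under_replicated
    if unbound_comp and strong_comp:
        print(f"under-replicated overlap: unbound-compensated "
              f"{overlap_fraction(ann, unbound_comp, ur) * 100:.0f}%, "
              f"strongly bound {overlap_fraction(ann, strong_comp, ur) * 100:.0f}%")
    bound_ids = list(x_calls.index[x_calls["bound"]])
    unbound_ids = list(x_calls.index[~x_calls["bound"]])
    print(f"housekeeping: {flag_fraction(study.housekeeping, bound_ids) * 100:.0f}% "
          f"of bound vs {flag_fraction(study.housekeeping, unbound_ids) * 100:.0f}% "
          f"of unbound genes")


if __name__ == "__main__":
    main()
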