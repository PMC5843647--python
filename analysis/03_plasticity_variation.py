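"""Genetic variation for plasticity: reaction norms, cross-environment
genetic correlations, PCA with per-component ANOVA, and expression
clustering.

For each tissue: per-family seasonal reaction norms on Z-transformed
expression; the paired comparison of across-family slope versus intercept
variability (less variable slopes = families agree on the plastic
response); cross-environment correlations of family means; two-way ANOVA
of season/family/interaction on leading PC scores of log10(CPM+1); and a
neighbour-joining tree of samples. Writes tables under results/plasticity/."""

from _common import RESULTS, load_cohort

from plastigene import (
    compare_slope_intercept,
    cpm,
    cross_env_correlation,
    euclidean_distances,
    filter_low_expression,
    io,
    nj_tree,
    pc_anova,
    pca,
    reaction_norms,
    tmm_factors,
    transform,
)


def main() -> None:
    out = RESULTS / "plasticity"
    out.mkdir(parents=True, exist_ok=True)
    for tissue, (counts, design, _) in load_cohort().items():
        filt = filter_low_expression(counts)
        cpm_mat = cpm(filt.counts, tmm_factors(filt.counts))
        z = transform(cpm_mat, "z_per_gene")
        log10 = transform(cpm_mat, "log10_cpm")

        rn = reaction_norms(z, design)
        rn.summary.to_csv(out / f"reaction_norms_{tissue}.tsv", sep="\t", index_label="gene")
        comp = compare_slope_intercept(rn, measure="sd")
        print(
            f"\n{tissue}: across-family slope SD vs intercept SD: median "
            f"difference {comp.median_pct_difference:+.0f}% "
            f"(signed-rank p = {comp.p:.2g}, n = {comp.n} genes)"
        )
        for method in ("pearson", "spearman"):
            corr = cross_env_correlation(z, design, method)
            corr.rho.to_csv(out / f"cross_env_{method}_{tissue}.tsv", sep="\t")
            print(f"  median cross-environment rho ({method}): {corr.median:+.2f}")

        pcs = pca(log10)
        assoc = pc_anova(pcs, design)
        assoc.to_csv(out / f"pc_anova_{tissue}.tsv", sep="\t", index=False)
        n_pcs = assoc["pc"].nunique()
        cum = pcs.variance_fraction[:n_pcs].sum()
        for term in ("season", "family", "season:family"):
            sig = assoc[(assoc["term"] == term) & (assoc["q"] < 0.05)]
            pcs_hit = ", ".join(sig["pc"]) if len(sig) else "none"
            print(
                f"  PCs associated with {term}: {pcs_hit} "
                f"(of first {n_pcs} PCs = {cum:.0%} of variance)"
            )

        dist = euclidean_distances(log10)
        io.write_phylip_distances(dist, out / f"distances_{tissue}.phy")
        io.write_newick(nj_tree(dist), out / f"nj_tree_{tissue}.nwk")
        print(f"  NJ tree of {dist.shape[0]} samples -> nj_tree_{tissue}.nwk")


if __name__ == "__main__":
    main()
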