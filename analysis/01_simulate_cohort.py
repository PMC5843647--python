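"""Simulate the reference cohort: 7 full-sib families x 2 seasons x 2 food
treatments, 72 samples per tissue, 2,000 genes, with known season, family,
food and GxE effects. Writes counts, design and truth tables under
results/data/<tissue>/."""

from _common import DATA, TISSUES, cohort_params

from plastigene import io, simulate_counts, simulate_design


def main() -> None:
    for tissue in TISSUES:
        params = cohort_params(tissue)
        design = simulate_design(params)
        counts, truth = simulate_counts(design, params)
        tdir = DATA / tissue
        tdir.mkdir(parents=True, exist_ok=True)
        io.write_counts(counts, tdir / "counts.tsv")
        io.write_design(design, tdir / "design.tsv")
        truth.to_csv(tdir / "truth.tsv", sep="\t", index_label="gene")
        print(
            f"{tissue}: {counts.shape[0]} genes x {counts.shape[1]} samples, "
            f"{int(truth['is_season'].sum())} season / "
            f"{int(truth['is_family'].sum())} family / "
            f"{int(truth['is_gxe'].sum())} GxE genes -> {tdir}"
        )


if __name__ == "__main__":
    main()
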