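"""Shared sample panel for the analysis scripts.

A small panel of synthetic cases emulating the recurrent clinical scenarios:
a biallelic FXN GAA expansion with strong length mosaicism, FGF14 expansions
with GGA stretches and a GAAGGA-dominant allele, a biallelic AAGGG-dominant
RFC1 expansion, FMR1 premutation and mosaic full-mutation males (with and
without CpG methylation), and a bipartite CTA/CTG ATXN8OS allele.
"""

from strtier.simulate import ReadLengthModel, SyntheticAlleleSpec, SyntheticSampleSpec

PANEL: dict[str, dict] = {
    "FXN_biallelic": dict(
        spec=SyntheticSampleSpec(
            locus_id="FXN",
            alleles=(
                SyntheticAlleleSpec(segments=(("GAA", 100),), jitter=6),
                SyntheticAlleleSpec(segments=(("GAA", 700),), jitter=120),
            ),
            coverage=20,
            substitution_rate=0.01,
            seed=101,
        ),
        ploidy=2,
    ),
    "FXN_carrier": dict(
        spec=SyntheticSampleSpec(
            locus_id="FXN",
            alleles=(
                SyntheticAlleleSpec(segments=(("GAA", 30),)),
                SyntheticAlleleSpec(segments=(("GAA", 700),), jitter=120),
            ),
            coverage=20,
            substitution_rate=0.01,
            seed=102,
        ),
        ploidy=2,
    ),
    "FGF14_mosaic_gga": dict(
        spec=SyntheticSampleSpec(
            locus_id="FGF14",
            alleles=(
                SyntheticAlleleSpec(segments=(("GAA", 41),)),
                SyntheticAlleleSpec(
                    segments=(("GAA", 300), ("GGA", 60), ("GAA", 90)), jitter=30
                ),
            ),
            coverage=20,
            substitution_rate=0.01,
            seed=103,
        ),
        ploidy=2,
    ),
    "FGF14_gaagga_dominant": dict(
        spec=SyntheticSampleSpec(
            locus_id="FGF14",
            alleles=(
                SyntheticAlleleSpec(segments=(("GAA", 36),)),
                SyntheticAlleleSpec(
                    segments=(("GAAGGA", 150), ("GAA", 30)), jitter=12
                ),
            ),
            coverage=20,
            substitution_rate=0.01,
            seed=104,
        ),
        ploidy=2,
    ),
    "RFC1_biallelic": dict(
        spec=SyntheticSampleSpec(
            locus_id="RFC1",
            alleles=(
                SyntheticAlleleSpec(segments=(("AAGGG", 450),), jitter=30),
                SyntheticAlleleSpec(
                    segments=(("AAGGG", 600), ("AAAGG", 80), ("AAGGG", 200)),
                    jitter=60,
                ),
            ),
            coverage=20,
            substitution_rate=0.01,
            read_length_model=ReadLengthModel(median_bp=4000, sigma=0.6),
            seed=105,
        ),
        ploidy=2,
    ),
    "FMR1_premutation_male": dict(
        spec=SyntheticSampleSpec(
            locus_id="FMR1",
            alleles=(
                SyntheticAlleleSpec(
                    segments=(("CGG", 130),), jitter=1, methylation_state=0.0
                ),
            ),
            coverage=15,
            substitution_rate=0.01,
            seed=106,
        ),
        ploidy=1,
    ),
    "FMR1_mosaic_male": dict(
        spec=SyntheticSampleSpec(
            locus_id="FMR1",
            alleles=(
                SyntheticAlleleSpec(
                    segments=(("CGG", 300),), jitter=60, methylation_state=0.9
                ),
                SyntheticAlleleSpec(
                    segments=(("CGG", 150), ("TGG", 40), ("CGG", 110)),
                    jitter=40,
                    methylation_state=0.0,
                ),
            ),
            coverage=15,
            substitution_rate=0.01,
            seed=107,
        ),
        # one X: the two "alleles" are mosaic cell populations of one allele
        ploidy=1,
    ),
    "ATXN8OS_expanded": dict(
        spec=SyntheticSampleSpec(
            locus_id="ATXN8OS",
            alleles=(
                SyntheticAlleleSpec(segments=(("CTA", 9), ("CTG", 9)),),
                SyntheticAlleleSpec(segments=(("CTA", 12), ("CTG", 84)), jitter=1),
            ),
            coverage=20,
            substitution_rate=0.01,
            seed=108,
        ),
        ploidy=2,
    ),
}
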