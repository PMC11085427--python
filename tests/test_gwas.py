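"""GWAS association curation: mapped-gene parsing, trait filtering, set building."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from flavogwas.errors import UsageError
from flavogwas.gwas import (
    GwasAssociation,
    TraitGeneSet,
    build_trait_gene_set,
    filter_associations,
    load_trait_rules,
    parse_mapped_genes,
    union_trait_sets,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("APOE - APOC1", {"APOE", "APOC1"}),
        ("no mapped genes x MYO6", {"MYO6"}),
        ("", set()),
        (None, set()),
        ("TNF - LTB", {"TNF", "LTB"}),
        ("A1;B1, C1", {"A1", "B1", "C1"}),
        ("intergenic", set()),
        ("CDKN2B-AS1", {"CDKN2B-AS1"}),  # hyphenated symbol is not a separator
    ],
)
def test_parse_mapped_genes(raw, expected):
    assert parse_mapped_genes(raw) == expected


def test_curated_variant_table_mapped_genes_parse_to_reported_gene():
    """Every mapped-gene string in the bundled GWAS-variant table parses to
    a set containing the reported priority gene (incl. the SNPxSNP
    interaction row mapping 'no mapped genes x MYO6')."""
    from flavogwas.datasets import load_gwas_variants

    frame = load_gwas_variants()
    for _, row in frame.iterrows():
        assert row["gene"] in parse_mapped_genes(row["mapped_genes"]), row["rsid"]


def _assoc(trait, gene="TNF", accession="GCST000001", rsid="rs1"):
    return GwasAssociation(
        accession=accession, trait=trait, rsid=rsid, mapped_gene_raw=gene
    )


class TestFilterAssociations:
    def test_default_hypertension_rules(self):
        rules = load_trait_rules()["hypertension"]
        rows = [
            _assoc("Hypertension"),
            _assoc("Pulmonary arterial hypertension"),
            _assoc("Preeclampsia or hypertension risk"),
            _assoc("Systolic blood pressure x hypertension"),
            _assoc("Early-onset hypertension"),
        ]
        kept = filter_associations(rows, rules["include"], rules["exclude"])
        assert [a.trait for a in kept] == [
            "Hypertension",
            "Systolic blood pressure x hypertension",
        ]

    def test_idempotent(self):
        rows = [_assoc("Hypertension"), _assoc("Atherosclerosis")]
        once = filter_associations(rows, ["hypertension"], ["pulmonary"])
        twice = filter_associations(once, ["hypertension"], ["pulmonary"])
        assert once == twice

    def test_empty_include_rejected(self):
        with pytest.raises(UsageError):
            filter_associations([_assoc("Hypertension")], [])

    def test_empty_exclude_keeps_all_matches(self):
        rows = [_assoc("Hypertension"), _assoc("hypertension, severe")]
        assert len(filter_associations(rows, ["hypertension"], [])) == 2


class TestBuildTraitGeneSet:
    def test_provenance_merging(self):
        rows = [
            _assoc("Hypertension", gene="A1", accession="GCST1", rsid="rs1"),
            _assoc("Hypertension", gene="A1 - B1", accession="GCST2", rsid="rs2"),
        ]
        ts = build_trait_gene_set(rows, "hypertension")
        assert ts.genes == {"A1", "B1"}
        assert len(ts.provenance["A1"]) == 2
        assert ts.n_associations == 2

    def test_all_unmapped_rows(self):
        rows = [_assoc("Hypertension", gene="no mapped genes") for _ in range(3)]
        ts = build_trait_gene_set(rows, "hypertension")
        assert ts.genes == frozenset()
        assert ts.n_associations == 3

    def test_matches_brute_force_enumeration(self):
        rng = random.Random(7)
        symbols = [f"GN{i}" for i in range(12)]
        rows = []
        for i in range(10):
            picked = rng.sample(symbols, rng.randint(1, 3))
            rows.append(
                _assoc("Hypertension", gene=" - ".join(picked),
                       accession=f"GCST{i}", rsid=f"rs{i}")
            )
        ts = build_trait_gene_set(rows, "hypertension")
        # oracle: loop every row, split by hand
        expected = {}
        for row in rows:
            for token in row.mapped_gene_raw.split(" - "):
                expected.setdefault(token.strip().upper(), set()).add(
                    (row.accession, row.rsid)
                )
        assert ts.genes == set(expected)
        for gene, prov in expected.items():
            assert ts.provenance[gene] == prov

    def test_orphan_provenance_rejected(self):
        with pytest.raises(UsageError, match="provenance"):
            TraitGeneSet(
                trait_label="hypertension",
                genes=frozenset({"TNF"}),
                provenance={},
                n_associations=1,
            )


class TestUnionTraitSets:
    def _trait(self, label, genes):
        rows = [
            _assoc("t", gene=g, accession=f"GCST_{label}_{g}", rsid=f"rs_{g}")
            for g in genes
        ]
        return build_trait_gene_set(rows, label)

    def test_merges_provenance(self):
        union = union_trait_sets(
            [self._trait("a", ["A", "B"]), self._trait("b", ["B", "C"])]
        )
        assert union.genes == {"A", "B", "C"}
        assert len(union.provenance["B"]) == 2
        assert union.by_trait["a"] == {"A", "B"}

    def test_disjoint_sizes_add(self):
        union = union_trait_sets(
            [self._trait("a", ["A", "B", "C"]), self._trait("b", ["D", "E", "F", "G"])]
        )
        assert len(union.genes) == 7

    @given(
        st.lists(
            st.sets(st.sampled_from([f"G{i}" for i in range(20)]), max_size=10),
            min_size=1,
            max_size=4,
        )
    )
    def test_union_bounded_by_sum(self, gene_sets):
        traits = [
            self._trait(f"t{i}", genes) for i, genes in enumerate(gene_sets)
        ]
        union = union_trait_sets(traits)
        assert union.genes == set().union(*gene_sets)
        assert len(union.genes) <= sum(len(g) for g in gene_sets)
        if gene_sets and all(
            not (a & b)
            for i, a in enumerate(gene_sets)
            for b in gene_sets[i + 1:]
        ):
            assert len(union.genes) == sum(len(g) for g in gene_sets)
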