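"""Contribution scoring on the combinatorial gene–organ model."""

import pytest

import floralquant as fq
from floralquant.model import (
    FloralModel,
    GeneClassSpec,
    ModelError,
    OrganSpec,
)
from floralquant.rounding import NO_ROUNDING, RoundingPolicy


def tiny_model(memberships, importances=None, nonbase=(), reproductive=(), early=()):
    """Build a small model from {organ: [classes]} membership lists."""
    organs = tuple(
        OrganSpec(
            name=o,
            whorl_index=k + 1,
            importance=(importances or {}).get(o, 1.0),
            required_classes=frozenset(cls),
        )
        for k, (o, cls) in enumerate(memberships.items())
    )
    genes = sorted({g for cls in memberships.values() for g in cls})
    gene_specs = tuple(
        GeneClassSpec(
            name=g,
            builds_organs=frozenset(o for o, cls in memberships.items() if g in cls),
            in_base_model=g not in nonbase,
        )
        for g in genes
    )
    return FloralModel(
        organs=organs,
        gene_classes=gene_specs,
        reproductive_organs=frozenset(reproductive),
        early_reproductive_classes=tuple(early),
    )


class TestBaseWeights:
    def test_default_model_unit_shares(self, model):
        w = fq.derive_base_organ_weights(model)
        assert w == {"sepals": 0.2, "petals": 0.3, "stamens": 0.3, "carpels": 0.2}

    def test_single_organ_single_gene(self):
        m = tiny_model({"organ": ["g"]})
        assert fq.derive_base_organ_weights(m) == {"organ": 1.0}

    def test_three_organ_counts_normalize(self):
        m = tiny_model({"o1": ["x"], "o2": ["y"], "o3": ["x", "y"]})
        assert fq.derive_base_organ_weights(m) == {"o1": 0.25, "o2": 0.25, "o3": 0.5}

    def test_weights_sum_to_one(self, model):
        assert sum(fq.derive_base_organ_weights(model).values()) == pytest.approx(1, abs=1e-12)


class TestMutantPhenotype:
    @pytest.mark.parametrize(
        "gene,expected",
        [
            ("A", {"stamens", "carpels"}),
            ("B", {"sepals", "carpels"}),
            ("CD", {"sepals", "petals"}),
            ("E", set()),
        ],
    )
    def test_complement_rule(self, model, gene, expected):
        assert fq.mutant_phenotype(model, gene) == expected

    def test_gene_building_nothing_forms_everything(self):
        m = tiny_model({"o1": ["x", "z"], "o2": ["y", "z"]})
        # x is absent from o2, y absent from o1; a class required nowhere
        # would leave all organs — emulate via override
        organs = tuple(m.organs)
        genes = tuple(m.gene_classes) + (GeneClassSpec(name="idle", builds_organs=frozenset()),)
        m2 = FloralModel(organs=organs, gene_classes=genes)
        assert fq.mutant_phenotype(m2, "idle") == {"o1", "o2"}
        assert fq.mutant_loss_value(m2, "idle", fq.derive_base_organ_weights(m2)) == pytest.approx(0)

    def test_unknown_gene_raises(self, model):
        with pytest.raises(ModelError):
            fq.mutant_phenotype(model, "Z")

    def test_override_table_wins(self, model):
        m = FloralModel(
            organs=model.organs,
            gene_classes=model.gene_classes,
            reproductive_organs=model.reproductive_organs,
            early_reproductive_classes=model.early_reproductive_classes,
            mutant_phenotype_overrides={"A": frozenset({"carpels"})},
        )
        assert fq.mutant_phenotype(m, "A") == {"carpels"}


class TestContributions:
    def test_losses(self, model, contributions):
        assert contributions.mutant_loss == pytest.approx(
            {"A": 0.5, "B": 0.6, "CD": 0.5, "E": 1.0}
        )

    def test_normalized_three_decimal(self, contributions):
        assert contributions.contributions == {
            "A": 0.192, "B": 0.231, "CD": 0.192, "E": 0.385,
        }

    def test_raw_values_without_rounding(self, model):
        res = fq.derive_contributions(model, rounding=NO_ROUNDING)
        assert res.contributions["A"] == pytest.approx(0.5 / 2.6, abs=1e-15)
        assert res.contributions["E"] == pytest.approx(1.0 / 2.6, abs=1e-15)
        assert sum(res.contributions.values()) == pytest.approx(1, abs=1e-12)

    def test_equal_losses_split_evenly(self):
        m = tiny_model({"o1": ["x"], "o2": ["y"]})
        res = fq.derive_contributions(m, rounding=NO_ROUNDING)
        assert res.contributions == {"x": 0.5, "y": 0.5}

    def test_truncation_gives_different_third_decimal(self, model):
        res = fq.derive_contributions(model, rounding=RoundingPolicy(3, "truncate"))
        assert res.contributions["B"] == 0.230  # 0.23077 truncated


class TestResidualContribution:
    def test_agl6_value(self, contributions):
        assert contributions.nonbase_contributions["AGL6"] == 0.077
        assert contributions.agl6_value == 0.077

    def test_empty_early_list_gives_reproductive_share(self, model, contributions):
        m = FloralModel(
            organs=model.organs,
            gene_classes=model.gene_classes,
            reproductive_organs=model.reproductive_organs,
            early_reproductive_classes=(),
        )
        v = fq.derive_nonbase_contribution(m, contributions.contributions, "AGL6")
        assert v == pytest.approx(0.5)

    def test_hypothetical_quarter_shares_cancel(self, model):
        v = fq.derive_nonbase_contribution(
            model, {"A": 0.25, "B": 0.25, "CD": 0.25, "E": 0.25}, "AGL6"
        )
        assert v == pytest.approx(0.0)

    def test_negative_residual_flagged(self, model):
        v = fq.derive_nonbase_contribution(
            model, {"A": 0.1, "B": 0.4, "CD": 0.4, "E": 0.1}, "AGL6"
        )
        assert v == pytest.approx(-0.3)

    def test_base_class_rejected(self, model, contributions):
        with pytest.raises(ModelError):
            fq.derive_nonbase_contribution(model, contributions.contributions, "E")


class TestCombinationTable:
    def test_full_set_petals(self, model, contributions):
        table = fq.combination_table(
            model, contributions.all_contributions, {"ALL": ["A", "B", "CD", "E", "AGL6"]}
        )
        assert table.cell("ALL", "petals") == 0.885

    def test_empty_subset_is_zero(self, model, contributions):
        table = fq.combination_table(model, contributions.all_contributions, {"none": []})
        assert all(v == 0 for v in table.rows["none"].values())

    def test_pair_sum(self, model, contributions):
        table = fq.combination_table(model, contributions.all_contributions, {"AB": ["A", "B"]})
        assert table.cell("AB", "petals") == 0.423  # 0.192 + 0.231

    def test_unknown_member_raises(self, model, contributions):
        with pytest.raises(ModelError):
            fq.combination_table(model, contributions.all_contributions, {"bad": ["Z"]})

    def test_full_base_set_matches_gradient_inputs(self, model, contributions):
        """Full-set cells equal the per-organ totals the gradients use."""
        table = fq.combination_table(
            model, contributions.contributions, {"base": ["A", "B", "CD", "E"]},
            rounding=NO_ROUNDING,
        )
        g = fq.gradient_values(model, contributions.contributions)
        for o in model.organs:
            assert table.cell("base", o.name) * o.importance == pytest.approx(
                g.values[o.name]
            )


class TestGradients:
    def test_computed_products(self, model, contributions):
        g = fq.gradient_values(model, contributions.contributions)
        assert g.provenance == "computed"
        assert g.values == pytest.approx(
            {"sepals": 0.577, "petals": 1.616, "stamens": 2.424, "carpels": 2.308}
        )

    def test_reference_vector(self, model, contributions):
        g = fq.gradient_values(model, contributions.contributions, mode="reference")
        assert g.provenance == "reference"
        assert g.values == {
            "sepals": 0.572, "petals": 1.606, "stamens": 2.409, "carpels": 2.288,
        }

    def test_unit_importance_equals_contribution_sums(self, contributions):
        m = tiny_model(
            {"o1": ["x", "z"], "o2": ["y", "z"]},
        )
        res = fq.derive_contributions(m, rounding=NO_ROUNDING)
        g = fq.gradient_values(m, res.contributions)
        for o in ("o1", "o2"):
            total = sum(res.contributions[c] for c in ("x", "y", "z")
                        if o in m.gene(c).builds_organs)
            assert g.values[o] == pytest.approx(total)


class TestInvariance:
    def test_label_permutation_leaves_values_unchanged(self, model, contributions):
        organs = tuple(reversed(model.organs))
        genes = tuple(reversed(model.gene_classes))
        permuted = FloralModel(
            organs=organs, gene_classes=genes,
            reproductive_organs=model.reproductive_organs,
            early_reproductive_classes=model.early_reproductive_classes,
        )
        res = fq.derive_contributions(permuted)
        assert res.contributions == contributions.contributions
        assert res.base_organ_weights == contributions.base_organ_weights
        assert res.nonbase_contributions == contributions.nonbase_contributions


class TestValidation:
    def test_inconsistent_membership_rejected(self):
        with pytest.raises(ModelError, match="inconsistent membership"):
            FloralModel(
                organs=(OrganSpec("o1", 1, 1.0, frozenset({"x"})),),
                gene_classes=(GeneClassSpec("x", frozenset()),),
            )

    def test_no_base_class_rejected(self):
        with pytest.raises(ModelError, match="base-model"):
            FloralModel(
                organs=(OrganSpec("o1", 1, 1.0, frozenset({"x"})),),
                gene_classes=(GeneClassSpec("x", frozenset({"o1"}), in_base_model=False),),
            )

    def test_yaml_roundtrip(self, tmp_path, model):
        doc = {
            "organs": [
                {"name": o.name, "whorl_index": o.whorl_index,
                 "importance": o.importance,
                 "required_classes": sorted(o.required_classes)}
                for o in model.organs
            ],
            "gene_classes": [
                {"name": g.name, "builds_organs": sorted(g.builds_organs),
                 "in_base_model": g.in_base_model}
                for g in model.gene_classes
            ],
            "reproductive_organs": sorted(model.reproductive_organs),
            "early_reproductive_classes": list(model.early_reproductive_classes),
        }
        import yaml

        p = tmp_path / "m.yaml"
        p.write_text(yaml.safe_dump(doc))
        m2 = fq.load_model(p)
        assert fq.derive_contributions(m2).contributions == {
            "A": 0.192, "B": 0.231, "CD": 0.192, "E": 0.385,
        }
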