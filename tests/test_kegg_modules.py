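"""Grammar, completeness, and rollup semantics for KEGG-style modules.

The evaluator is checked against an independent oracle that compiles each
parsed definition into a plain Python boolean expression and enumerates every
subset of its leaf KOs.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from spongefunc.expression import PeptideExpression
from spongefunc.io_formats import ModuleCatalog, OrfAnnotation, PathwayCatalog
from spongefunc.kegg_modules import (
    Alternative,
    Complex,
    DefinitionParseError,
    Leaf,
    OptionalPart,
    StepSequence,
    evaluate_completeness,
    is_satisfied,
    ko_multiplicity,
    leaf_kos,
    module_expression,
    hierarchy_rollup,
    parse_definition,
    pathway_expression,
    serialize,
    taxon_split_expression,
)
from spongefunc.synthetic import random_module_definition


def compile_to_python(node) -> str:
    """Independent semantics: render the tree as a Python boolean expression
    over a present-set variable P."""
    if isinstance(node, Leaf):
        return f'("{node.ko}" in P)'
    if isinstance(node, OptionalPart):
        return "True"
    if isinstance(node, Complex):
        return "(" + " and ".join(compile_to_python(p) for p in node.parts) + ")"
    if isinstance(node, Alternative):
        return "(" + " or ".join(compile_to_python(o) for o in node.options) + ")"
    if isinstance(node, StepSequence):
        return "(" + " and ".join(compile_to_python(s) for s in node.steps) + ")"
    raise TypeError(node)


def oracle_satisfied(node, present: frozenset) -> bool:
    return eval(compile_to_python(node), {"P": present})  # noqa: S307 - test oracle


class TestParser:
    def test_single_ko_is_leaf(self):
        assert parse_definition("K00001") == Leaf("K00001")

    def test_complex_then_alternative_steps(self):
        tree = parse_definition("K1+K2 K3,K4")
        assert tree == StepSequence(
            (Complex((Leaf("K1"), Leaf("K2"))), Alternative((Leaf("K3"), Leaf("K4"))))
        )

    def test_parenthesized_alternative_inside_complex(self):
        # (K1,K2)+K3 must be satisfied by {K1,K3} and {K2,K3} but not {K1,K2}
        tree = parse_definition("(K1,K2)+K3")
        assert is_satisfied(tree, frozenset({"K1", "K3"}))
        assert is_satisfied(tree, frozenset({"K2", "K3"}))
        assert not is_satisfied(tree, frozenset({"K1", "K2"}))
        assert not is_satisfied(tree, frozenset({"K3"}))

    @pytest.mark.parametrize(
        "bad",
        ["(K1 K2", "K1+", "K1,,K2", "K1 + K2)", ""],
    )
    def test_malformed_definitions_rejected_with_position(self, bad):
        with pytest.raises(DefinitionParseError) as err:
            parse_definition(bad)
        assert err.value.position >= 0

    def test_optional_component_marked(self):
        tree = parse_definition("K1-K2+K3")
        assert isinstance(tree, Complex)
        assert any(isinstance(p, OptionalPart) for p in tree.parts)


class TestSemanticEquivalence:
    """parse -> serialize -> parse preserves satisfying sets (exhaustive)."""

    @pytest.mark.parametrize("seed", range(30))
    def test_roundtrip_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_leaves = int(rng.integers(1, 9))
        definition = random_module_definition(rng, n_leaves)
        tree = parse_definition(definition)
        tree2 = parse_definition(serialize(tree))
        kos = leaf_kos(tree)
        assert set(kos) == set(leaf_kos(tree2))
        for r in range(len(kos) + 1):
            for subset in itertools.combinations(kos, r):
                present = frozenset(subset)
                expected = oracle_satisfied(tree, present)
                assert is_satisfied(tree, present) == expected
                assert is_satisfied(tree2, present) == expected


class TestCompleteness:
    def test_two_required_steps(self):
        tree = parse_definition("K1 K2")
        assert evaluate_completeness(tree, {"K1", "K2"}) == (True, 1.0)
        assert evaluate_completeness(tree, {"K1"}) == (False, 0.5)

    def test_alternative_satisfied_by_either_option(self):
        tree = parse_definition("K1,K2")
        assert evaluate_completeness(tree, {"K2"}) == (True, 1.0)

    def test_complex_step_fraction_against_enumeration(self):
        tree = parse_definition("(K1+K2) K3")
        # oracle: step 1 needs both K1 and K2, step 2 needs K3
        for subset in itertools.chain.from_iterable(
            itertools.combinations(("K1", "K2", "K3"), r) for r in range(4)
        ):
            present = set(subset)
            want_steps = ("K1" in present and "K2" in present, "K3" in present)
            complete, frac = evaluate_completeness(tree, present)
            assert frac == sum(want_steps) / 2
            assert complete == all(want_steps)
        assert evaluate_completeness(tree, {"K1", "K3"}) == (False, 0.5)

    def test_optional_step_not_counted(self):
        tree = parse_definition("K1+K2-K3")
        assert evaluate_completeness(tree, {"K1", "K2"}) == (True, 1.0)


@pytest.fixture
def tiny_catalog():
    entries = pd.DataFrame(
        {
            "module_id": ["M1", "M2", "M3"],
            "name": ["one", "two", "three"],
            "level_B": ["Energy", "Energy", "Transport"],
            "level_C": ["N", "C", "ABC"],
            "definition": ["K1 K2", "K1+K3", "K4,K5"],
        }
    )
    return ModuleCatalog(entries=entries)


class TestModuleExpression:
    def test_additivity_and_shared_ko_counts_in_both(self, tiny_catalog):
        tpm = pd.DataFrame(
            {"s1": [100.0, 50.0, 25.0], "s2": [10.0, 20.0, 30.0]},
            index=pd.Index(["K1", "K2", "K3"], name="ko"),
        )
        profile = module_expression(tpm, tiny_catalog)
        assert profile.expression.loc["M1", "s1"] == 150.0
        assert profile.expression.loc["M2", "s1"] == 125.0  # K1 counted fully again
        assert profile.expression.loc["M3", "s1"] == 0.0
        assert profile.expression[["s1"]].sum().iloc[0] > tpm["s1"].sum()
        assert profile.complete.loc["M1"] and profile.complete.loc["M2"]
        assert not profile.complete.loc["M3"]
        assert profile.atpm.loc["M1"] == pytest.approx((150 + 30) / 2)

    def test_empty_ko_matrix_all_zero_incomplete(self, tiny_catalog):
        tpm = pd.DataFrame(columns=["s1"], index=pd.Index([], name="ko"), dtype=float)
        profile = module_expression(tpm, tiny_catalog)
        assert (profile.expression["s1"] == 0).all()
        assert not profile.complete.any()

    def test_monotone_in_ko_expression(self, tiny_catalog):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(
            rng.uniform(0, 100, (5, 3)),
            index=pd.Index([f"K{i}" for i in range(1, 6)], name="ko"),
            columns=["s1", "s2", "s3"],
        )
        more = base + rng.uniform(0, 10, base.shape)
        low = module_expression(base, tiny_catalog).expression
        high = module_expression(more, tiny_catalog).expression
        assert (high.to_numpy() >= low.to_numpy() - 1e-12).all()

    def test_hierarchy_rollup_sums_members(self, tiny_catalog):
        tpm = pd.DataFrame(
            {"s1": [1.0, 2.0, 4.0, 8.0]},
            index=pd.Index(["K1", "K2", "K3", "K4"], name="ko"),
        )
        profile = module_expression(tpm, tiny_catalog)
        rolled = hierarchy_rollup(profile, "level_B")
        assert rolled.loc["Energy", "s1"] == profile.expression.loc[["M1", "M2"], "s1"].sum()

    def test_pathway_rollup_flat_membership(self, tiny_catalog):
        tpm = pd.DataFrame(
            {"s1": [1.0, 2.0]}, index=pd.Index(["K1", "K2"], name="ko")
        )
        pathways = PathwayCatalog(
            entries=pd.DataFrame(
                {
                    "pathway_id": ["P1"],
                    "name": ["p"],
                    "level_A": ["Metabolism"],
                    "level_B": ["Energy"],
                    "kos": [("K1", "K2", "K9")],
                }
            )
        )
        out = pathway_expression(tpm, pathways)
        assert out.loc["P1", "s1"] == 3.0


class TestTaxonSplit:
    def test_split_partitions_module_expression(self, tiny_catalog):
        tpm = pd.DataFrame(
            {"s1": [60.0, 40.0, 10.0], "s2": [5.0, 15.0, 0.0]},
            index=pd.Index(["p1", "p2", "p3"], name="peptide_id"),
        )
        ann = OrfAnnotation(
            records=pd.DataFrame(
                {
                    "transcript_id": ["t1", "t2", "t3"],
                    "peptide_id": ["p1", "p2", "p3"],
                    "peptide_length": [100, 100, 100],
                    "ko": ["K1", "K1", "K2"],
                    "taxon": [
                        "Bacteria;Chloroflexi;c;o;f;g",
                        "Bacteria;Proteobacteria;c;o;f;g",
                        None,
                    ],
                }
            )
        )
        pe = PeptideExpression(counts=tpm, lengths=ann.lengths().astype(float), tpm=tpm)
        split = taxon_split_expression(pe, ann, tiny_catalog, rank="phylum")
        m1 = split.loc["M1"]
        assert m1.loc["Chloroflexi", "s1"] == 60.0
        assert m1.loc["Proteobacteria", "s1"] == 40.0
        assert m1.loc["unclassified", "s1"] == 10.0
        # exact partition of the module total
        ko_total = tpm.loc[["p1", "p2"]].sum() + tpm.loc[["p3"]].sum()
        assert np.allclose(m1.sum(axis=0), ko_total)


class TestKoMultiplicity:
    def test_counts_containing_modules(self, tiny_catalog):
        mult = ko_multiplicity(tiny_catalog)
        assert mult.loc["K1", "n_modules"] == 2
        assert mult.loc["K2", "n_modules"] == 1
        assert mult.attrs["frac_multiple"] == pytest.approx(1 / 5)

    def test_disjoint_catalog_all_single(self):
        entries = pd.DataFrame(
            {
                "module_id": ["M1", "M2"],
                "name": ["a", "b"],
                "level_B": ["x", "x"],
                "level_C": ["y", "y"],
                "definition": ["K1 K2", "K3,K4"],
            }
        )
        mult = ko_multiplicity(ModuleCatalog(entries=entries))
        assert (mult["multiplicity"] == 1).all()
        assert mult.attrs["frac_multiple"] == 0.0
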