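"""Model representation, grammar, df accounting, identification screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from singlesem import (
    ModelError,
    ModelSyntaxError,
    ParamCell,
    SampleMoments,
    SemModel,
    check_empirical_identification,
    count_df,
    parse_model,
    serialize_model,
)
from singlesem.fixtures import (
    build_fixture,
    loop_simplex_skeleton,
    structured_pairs_population,
)

FIGURE_STYLE_TEXT = """
# four latents, two indicators each, latent causal structure,
# fixed error variances on the four scaling indicators
LATENT eta1 eta2 eta3 eta4
INDICATOR y1 y2 y3 y4 y5 y6 y7 y8
LOAD y1 eta1 FIXED 1.0
LOAD y2 eta1 FREE
LOAD y3 eta2 FIXED 1.0
LOAD y4 eta2 FREE
LOAD y5 eta3 FIXED 1.0
LOAD y6 eta3 FREE START 0.8
LOAD y7 eta4 FIXED 1.0
LOAD y8 eta4 FREE
EFFECT eta1 eta3 FREE
EFFECT eta2 eta3 FREE
EFFECT eta3 eta4 FREE
PSI eta1 eta2 FREE
ERRVAR y1 FIXED 0.3
ERRVAR y3 FIXED 0.25
ERRVAR y5 FIXED 0.35
ERRVAR y7 FIXED_PCT 20
"""


class TestParser:
    def test_structured_model_text(self):
        model = parse_model(FIGURE_STYLE_TEXT)
        assert model.m == 4 and model.p == 8
        # four scaling loads fixed at 1.0
        fixed_loads = [
            (i, j)
            for i in range(8)
            for j in range(4)
            if model.Lambda[i, j].status == "fixed" and model.Lambda[i, j].value == 1.0
        ]
        assert len(fixed_loads) == 4
        # undeclared variances defaulted to free; df matches the structured fixture
        audit = count_df(model)
        assert (audit.n_moments, audit.n_free, audit.df) == (36, 16, 20)

    def test_saturated_latent_block_from_text(self):
        lines = [
            "LATENT e1 e2 e3",
            "INDICATOR y1 y2 y3",
            "LOAD y1 e1 FIXED 1.0",
            "LOAD y2 e2 FIXED 1.0",
            "LOAD y3 e3 FIXED 1.0",
            "ERRVAR y1 FIXED 0.1",
            "ERRVAR y2 FIXED 0.1",
            "ERRVAR y3 FIXED 0.1",
            "PSI e1 e2 FREE",
            "PSI e1 e3 FREE",
            "PSI e2 e3 FREE",
        ]
        model = parse_model("\n".join(lines))
        audit = count_df(model)
        # saturated: 6 free latent (co)variances, nothing else free
        assert audit.breakdown["Psi"] == 6
        assert audit.df == 0

    def test_undeclared_name_is_error(self):
        bad = "LATENT eta1\nINDICATOR y1\nLOAD y1 eta1 FIXED 1.0\nLOAD y2 eta1 FREE\nERRVAR y1 FIXED 0.2\n"
        with pytest.raises(ModelSyntaxError, match="unknown indicator 'y2'"):
            parse_model(bad)

    @pytest.mark.parametrize(
        "text, match",
        [
            ("LATENT e\nINDICATOR y\nLOAD y e FIXED\n", "FIXED requires"),
            ("LATENT e\nINDICATOR y\nLOAD y e FIXED 1.0\nLOAD y e FREE\nERRVAR y FIXED 0.1\n", "duplicate"),
            ("LATENT e\nINDICATOR y\nLOAD y e FREE\nERRVAR y FREE\n", "no scale"),
            ("LATENT e\nINDICATOR y\nLOAD y e FIXED 1.0\nERRVAR y FIXED -0.5\n", "negative fixed error"),
            ("LATENT e\nINDICATOR y\nFROB y e 1\n", "unknown keyword"),
            ("LATENT e\nINDICATOR y\nLOAD y e FIXED 1.0\nERRVAR y FIXED_PCT 120\n", r"\[0, 100\]"),
        ],
    )
    def test_grammar_errors(self, text, match):
        with pytest.raises(ModelError, match=match):
            parse_model(text)

    def test_syntax_error_carries_line_number(self):
        text = "LATENT e\nINDICATOR y\nLOAD y e FIXED 1.0\nERRVAR y BANANA\n"
        with pytest.raises(ModelSyntaxError, match="line 4"):
            parse_model(text)

    @pytest.mark.parametrize("name", ["saturated_pairs", "structured_pairs", "loop_simplex"])
    def test_serialize_round_trip(self, name):
        model = build_fixture(name)
        text = serialize_model(model)
        reparsed = parse_model(text)
        assert serialize_model(reparsed) == text
        a, b = count_df(model), count_df(reparsed)
        assert (a.n_moments, a.n_free, a.df) == (b.n_moments, b.n_free, b.df)

    def test_equality_groups_parse_and_pool(self):
        text = (
            "LATENT e m\nINDICATOR y1 y2 y3\n"
            "LOAD y1 e FIXED 1.0\nERRVAR y1 FIXED 0.2\n"
            "LOAD y2 e FREE\nLOAD y3 e FREE\n"
            "PSI m m FIXED 1.0\n"
            "EQ mload LOAD y1 m ; LOAD y2 m ; LOAD y3 m\n"
        )
        model = parse_model(text)
        names = [fp.name for fp in model.free_parameters()]
        assert names.count("eq:mload") == 1
        group = next(fp for fp in model.free_parameters() if fp.name == "eq:mload")
        assert len(group.cells) == 3


class TestDfAudit:
    def test_saturated_pairs_counts(self):
        audit = count_df(build_fixture("saturated_pairs"))
        assert audit.n_moments == 36
        assert audit.n_free == 22
        assert audit.df == 14
        assert audit.breakdown == {"Lambda": 4, "B": 0, "Psi": 10, "Theta": 8}

    def test_structured_pairs_counts(self):
        audit = count_df(build_fixture("structured_pairs"))
        assert audit.df == 20
        # two fewer latent-level parameters than the saturated block's ten
        assert audit.breakdown["B"] + audit.breakdown["Psi"] == 8
        # four fixed scaling-indicator error variances
        assert audit.breakdown["Theta"] == 4

    def test_saturated_moments_model_has_zero_df(self):
        # every moment free: one latent per indicator with saturated Psi, Theta=0
        p = 3
        model = SemModel([f"e{i}" for i in range(p)], [f"y{i}" for i in range(p)])
        for i in range(p):
            model.set_loading(f"y{i}", f"e{i}", ParamCell("fixed", 1.0))
            for j in range(i + 1):
                model.set_psi(f"e{j}", f"e{i}", ParamCell("free", None))
        audit = count_df(model)
        assert audit.n_moments == audit.n_free == 6
        assert audit.df == 0 and not audit.under_determined

    def test_negative_df_flagged_not_raised(self):
        model = SemModel(["e"], ["y"])
        model.set_loading("y", "e", ParamCell("fixed", 1.0))
        model.set_psi("e", "e", ParamCell("free", None))
        model.set_theta("y", "y", ParamCell("free", None))
        audit = count_df(model)
        assert audit.df == -1 and audit.under_determined

    @given(k=st.integers(min_value=2, max_value=8))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_equality_merge_reduces_free_count_by_k_minus_1(self, k):
        """Pooling k free loadings into one label removes exactly k-1 parameters."""
        latents = ["e", "m"]
        indicators = [f"y{i}" for i in range(k)]
        base = SemModel(latents, indicators)
        base.set_loading("y0", "e", ParamCell("fixed", 1.0))
        base.set_theta("y0", "y0", ParamCell("fixed", 0.2))
        base.set_psi("m", "m", ParamCell("fixed", 1.0))
        base.set_psi("e", "e", ParamCell("free", None))
        for i in range(k):
            base.set_theta(f"y{i}", f"y{i}", ParamCell("free", None))
        for i in range(k):
            base.set_loading(f"y{i}", "m", ParamCell("free", None))
        n_before = count_df(base).n_free
        pooled = base.copy()
        for i in range(k):
            pooled.set_loading(f"y{i}", "m", ParamCell("free", None, label="mload"))
        assert count_df(pooled).n_free == n_before - (k - 1)


class TestEmpiricalIdentification:
    def test_clean_on_population_from_same_structure(self, structured_model):
        report = check_empirical_identification(structured_model, structured_pairs_population())
        assert report.clean

    def test_zero_variance_flag(self, structured_model, structured_pop):
        S = structured_pop.S.copy()
        S[0, :] = 0.0
        S[:, 0] = 0.0
        report = check_empirical_identification(
            structured_model, SampleMoments(S, 500, structured_pop.variable_names)
        )
        assert report.zero_variance == ["y1"]

    def test_redundant_indicator_flag(self, structured_model, structured_pop):
        S = structured_pop.S.copy()
        S[1, :] = S[0, :]
        S[:, 1] = S[:, 0]
        S[1, 1] = S[0, 0]
        report = check_empirical_identification(
            structured_model, SampleMoments(S, 500, structured_pop.variable_names)
        )
        assert ("y1", "y2", pytest.approx(1.0)) in [
            (a, b, pytest.approx(r)) for a, b, r in report.redundant_pairs
        ]

    def test_disconnected_indicator_flag(self, structured_pop):
        model = build_fixture("structured_pairs")
        # orphan y8: remove its only loading
        model.set_loading("y8", "eta4", ParamCell("fixed", 0.0))
        report = check_empirical_identification(model, structured_pop)
        assert "y8" in report.disconnected

    def test_structural_underidentification_detected_by_rank(self, structured_pop):
        # freeing a scaling loading while its latent variance is free: rank drops
        model = build_fixture("structured_pairs")
        model.set_loading("y1", "eta1", ParamCell("free", 1.0))
        report = check_empirical_identification(model, structured_pop)
        assert report.rank_deficient
        assert report.jacobian_rank < report.n_free

    def test_dimension_mismatch_raises(self, structured_model):
        with pytest.raises(ModelError, match="p=8"):
            check_empirical_identification(structured_model, np.eye(5))


class TestFixedPct:
    def test_loop_simplex_has_ten_pct_declarations(self):
        model = loop_simplex_skeleton()
        pct_cells = [
            model.Theta[i, i].pct for i in range(model.p) if model.Theta[i, i].pct is not None
        ]
        assert pct_cells == [3.0] * 10

    def test_resolution_against_diagonal(self):
        model = loop_simplex_skeleton(n_occasions=3)
        S = np.diag([2.0, 4.0, 8.0]) + 0.5
        resolved = model.resolve_fixed_pct(S)
        vals = [resolved.Theta[i, i].value for i in range(3)]
        assert vals == pytest.approx([0.075, 0.135, 0.255])
        # original untouched (symbolic until resolved)
        assert model.Theta[0, 0].value is None
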