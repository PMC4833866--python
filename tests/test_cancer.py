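"""Alteration classification rules and combined per-sample summaries."""

import numpy as np
import pandas as pd
import pytest

from gisnet.cancer import (
    call_alterations,
    classify_mutation,
    select_ts_candidates,
    summarize_samples,
)


@pytest.mark.parametrize(
    "vclass, ndamage, expected",
    [
        ("nonsense", None, "lof"),
        ("frameshift_insertion", None, "lof"),
        ("frameshift_deletion", None, "lof"),
        ("inframe_insertion", None, "lof"),
        ("inframe_deletion", None, "lof"),
        ("splice_site", None, "lof"),
        ("missense", 5, "deleterious_missense"),
        ("missense", 6, "deleterious_missense"),
        ("missense", 4, "other"),
        ("missense", None, "other"),
        ("silent", None, "other"),
        ("weird_class", None, "other"),
    ],
)
def test_classify_mutation(vclass, ndamage, expected):
    assert classify_mutation(vclass, ndamage) == expected


def test_select_ts_candidates_tiers():
    ann = pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "s_score": [-2.3, -1.97, -1.5, 0.4],
    })
    out = select_ts_candidates(ann).set_index("gene")
    assert out.loc["a", "tier"] == "strict"
    assert out.loc["b", "tier"] == "borderline"
    assert "c" not in out.index and "d" not in out.index


def test_select_oncogene_direction():
    ann = pd.DataFrame({"gene": ["a", "b"], "s_score": [2.4, 1.0]})
    out = select_ts_candidates(ann, direction="onc")
    assert list(out["gene"]) == ["a"]


def _matrices(rows, genes, values):
    return pd.DataFrame(values, index=rows, columns=genes, dtype=float)


class TestCallRules:
    GENES = ["g1"]
    SAMPLES = ["s1"]

    def _call(self, gistic, z, meth, muts=None):
        mutations = muts if muts is not None else pd.DataFrame(
            columns=["sample", "gene", "variant_class", "ndamage"]
        )
        return call_alterations(
            mutations,
            _matrices(self.SAMPLES, self.GENES, [[gistic]]),
            _matrices(self.SAMPLES, self.GENES, [[z]]),
            _matrices(self.SAMPLES, self.GENES, [[meth]]),
            self.GENES,
        )

    def test_cn_reduced_low_expression(self):
        calls = self._call(-1, -2.5, 0)
        assert list(calls["category"]) == ["cn_reduced_low_expression"]

    def test_silencing_requires_no_copy_loss(self):
        calls = self._call(0, -2.5, 1)
        assert list(calls["category"]) == ["silenced"]
        calls = self._call(-1, -2.5, 1)
        assert "silenced" not in set(calls["category"])

    def test_z_above_threshold_no_call(self):
        assert self._call(-1, -1.0, 0).empty

    def test_homdel_counts_as_reduced(self):
        calls = self._call(-2, -3.0, 0)
        assert list(calls["category"]) == ["cn_reduced_low_expression"]

    def test_lof_mutation_call(self):
        muts = pd.DataFrame({
            "sample": ["s1"], "gene": ["g1"],
            "variant_class": ["nonsense"], "ndamage": [np.nan],
        })
        calls = self._call(0, 0.0, 0, muts)
        assert list(calls["category"]) == ["lof_mutation"]

    def test_unavailable_platform_leaves_unassessed(self):
        avail = pd.DataFrame(
            {"mutation": [True], "cnv": [False], "expression": [True],
             "methylation": [True]},
            index=self.SAMPLES,
        )
        calls = call_alterations(
            pd.DataFrame(columns=["sample", "gene", "variant_class", "ndamage"]),
            _matrices(self.SAMPLES, self.GENES, [[-1]]),
            _matrices(self.SAMPLES, self.GENES, [[-3.0]]),
            _matrices(self.SAMPLES, self.GENES, [[0]]),
            self.GENES,
            availability=avail,
        )
        assert calls.empty  # CN loss present but platform marked unavailable

    def test_threshold_monotonicity(self):
        """Tightening Z never increases the number of calls."""
        base = self._call(-1, -2.5, 0)
        tighter = call_alterations(
            pd.DataFrame(columns=["sample", "gene", "variant_class", "ndamage"]),
            _matrices(self.SAMPLES, self.GENES, [[-1]]),
            _matrices(self.SAMPLES, self.GENES, [[-2.5]]),
            _matrices(self.SAMPLES, self.GENES, [[0]]),
            self.GENES,
            z_threshold=-3.0,
        )
        assert len(tighter) <= len(base)


def test_idempotent_and_deterministic():
    muts = pd.DataFrame({
        "sample": ["s1"], "gene": ["g1"],
        "variant_class": ["missense"], "ndamage": [6],
    })
    mats = (
        _matrices(["s1"], ["g1"], [[0]]),
        _matrices(["s1"], ["g1"], [[0.0]]),
        _matrices(["s1"], ["g1"], [[0]]),
    )
    a = call_alterations(muts, *mats, ["g1"])
    b = call_alterations(muts, *mats, ["g1"])
    pd.testing.assert_frame_equal(a, b)
    assert list(a["category"]) == ["deleterious_missense"]


class TestSummaries:
    def test_worked_fraction_example(self):
        rows = []
        # 4 samples mutation only, 3 cn only, 1 both, 2 none
        for i in range(4):
            rows.append((f"m{i}", "g", "lof_mutation"))
        for i in range(3):
            rows.append((f"c{i}", "g", "cn_reduced_low_expression"))
        rows.append(("b0", "g", "lof_mutation"))
        rows.append(("b0", "g2", "cn_reduced_low_expression"))
        calls = pd.DataFrame(rows, columns=["sample", "gene", "category"])
        samples = [r[0] for r in rows] + ["n0", "n1"]
        summary = summarize_samples(calls, sorted(set(samples)))
        f = summary["lof_only"]["fractions"]
        assert f["mutation_only"] == pytest.approx(0.4)
        assert f["cn_expr_only"] == pytest.approx(0.3)
        assert f["mutation_and_cn"] == pytest.approx(0.1)
        assert f["none"] == pytest.approx(0.2)
        assert sum(f.values()) == pytest.approx(1.0)

    def test_planted_prevalence_recovered(self, small_cohort):
        cfg, tables, truth = small_cohort
        candidates = sorted(truth.planted_genes)
        calls = call_alterations(
            tables["mutations"], tables["cnv"], tables["expression_z"],
            tables["methylation"], candidates,
            availability=tables["availability"],
        )
        avail = tables["availability"]
        assessed = avail.index[avail.any(axis=1)].tolist()
        summary = summarize_samples(calls, assessed)
        # planted genes are altered far more often than background genes
        rng = np.random.default_rng(5)
        background = [
            g for g in tables["annotations"]["gene"]
            if g not in truth.planted_genes
        ]
        bg_sample = list(rng.choice(background, size=len(candidates), replace=False))
        bg_calls = call_alterations(
            tables["mutations"], tables["cnv"], tables["expression_z"],
            tables["methylation"], bg_sample,
            availability=tables["availability"],
        )
        bg_summary = summarize_samples(bg_calls, assessed)
        assert (
            summary["lof_only"]["fraction_altered"]
            > bg_summary["lof_only"]["fraction_altered"]
        )

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize_samples(pd.DataFrame(columns=["sample", "gene", "category"]), [])
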