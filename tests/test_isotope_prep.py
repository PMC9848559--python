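"""Lipid normalisation, TEF attachment, taxon pooling and source summaries."""

import numpy as np
import pytest
from scipy import stats

from isoweb.isotope_prep import (
    DEFAULT_TEF_TABLE,
    attach_tefs,
    lipid_correct,
    make_unknown_producer,
    pool_taxa,
    summarize_sources,
)
from isoweb.types import IsotopeSample


def sample(taxon="t", d13C=-25.0, d15N=5.0, **kw):
    return IsotopeSample(taxon, d13C, d15N, **kw)


class TestLipidCorrect:
    def test_below_threshold_passthrough(self):
        s = sample(whole_body=True, c_to_n=3.2)
        assert lipid_correct(s) == s

    def test_hand_computed_shift(self):
        s = sample(d13C=-30.0, whole_body=True, c_to_n=7.0)
        out = lipid_correct(s)
        assert out.d13C == pytest.approx(-30.0 - 3.32 + 0.99 * 7.0)
        assert out.d13C == pytest.approx(-26.39)
        assert out.d15N == s.d15N

    def test_formula_root_below_gate_is_untouched(self):
        # C:N = 3.32/0.99 would give a zero shift but sits below the 3.5 gate
        s = sample(whole_body=True, c_to_n=3.32 / 0.99)
        assert lipid_correct(s) == s

    def test_idempotent(self):
        s = sample(d13C=-30.0, whole_body=True, c_to_n=7.0)
        once = lipid_correct(s)
        assert lipid_correct(once) == once

    def test_non_whole_body_untouched(self):
        s = sample(c_to_n=8.0)
        assert lipid_correct(s) == s

    def test_missing_cn_is_an_error(self):
        with pytest.raises(ValueError, match="C:N"):
            lipid_correct(sample(whole_body=True))


class TestSummarizeSources:
    def test_hand_computed_mean_sd(self):
        out = summarize_sources({"t": [sample(d13C=-20.0), sample(d13C=-22.0)]})
        assert out["t"].mean_d13C == pytest.approx(-21.0)
        assert out["t"].sd_d13C == pytest.approx(np.sqrt(2.0), abs=1e-4)

    def test_identical_samples_zero_sd(self):
        out = summarize_sources({"t": [sample(), sample(), sample()]})
        assert out["t"].sd_d13C == 0.0 and out["t"].sd_d15N == 0.0

    def test_single_sample_needs_whitelist(self):
        with pytest.raises(ValueError):
            summarize_sources({"Copepoda": [sample("Copepoda")]})
        out = summarize_sources(
            {"Copepoda": [sample("Copepoda")]},
            single_sample_whitelist={"Copepoda"},
        )
        assert out["Copepoda"].sd_d13C == 0.5  # documented SD floor
        assert out["Copepoda"].mean_d13C == -25.0

    def test_two_samples_warns_below_recommended_three(self):
        with pytest.warns(UserWarning, match="minimum of 3"):
            summarize_sources({"t": [sample(), sample(d13C=-24.0)]})


class TestAttachTefs:
    def summaries(self):
        return summarize_sources({"prey": [sample("prey"), sample("prey", -24.0)]})

    def test_generic_d13c_default(self):
        (spec,) = attach_tefs(self.summaries(), group_map={"prey": "invertebrate"})
        assert (spec.tef_d13C, spec.tef_sd_d13C) == (0.4, 1.3)

    def test_taxon_table_lookup(self):
        (spec,) = attach_tefs(
            self.summaries(),
            tef_table={"invertebrate": (2.5, 0.5)},
            group_map={"prey": "invertebrate"},
        )
        assert (spec.tef_d15N, spec.tef_sd_d15N) == (2.5, 0.5)

    def test_missing_entry_without_fallback_raises(self):
        with pytest.raises(KeyError, match="prey"):
            attach_tefs(self.summaries(), tef_table={"fish": (3.4, 1.0)})

    def test_zero_tef_override_gives_tef_free_mixing(self):
        (spec,) = attach_tefs(
            self.summaries(),
            group_map={"prey": "invertebrate"},
            generic_d13c=(0.0, 0.0),
        )
        assert spec.means[0] + spec.tef_means[0] == spec.mean_d13C


class TestPoolTaxa:
    def test_identical_values_pooled(self):
        s = {
            "a": [sample("a", -25.0, 5.0), sample("a", -25.1, 5.1)],
            "b": [sample("b", -25.0, 5.0), sample("b", -25.1, 5.1)],
        }
        out, report = pool_taxa(s, [(("a", "b"), "genus")])
        assert "genus" in out and "a" not in out and "b" not in out
        assert report.decisions[0].pooled
        assert len(out["genus"]) == 4  # sample count conserved

    def test_widely_separated_not_pooled(self):
        rng = np.random.default_rng(0)
        s = {
            "a": [sample("a", c, n) for c, n in zip(
                rng.normal(-30, 0.5, 10), rng.normal(0, 0.5, 10))],
            "b": [sample("b", c, n) for c, n in zip(
                rng.normal(-20, 0.5, 10), rng.normal(10, 0.5, 10))],
        }
        out, report = pool_taxa(s, [(("a", "b"), "genus")])
        assert not report.decisions[0].pooled
        assert "a" in out and "b" in out

    def test_small_taxa_excluded_with_warning(self):
        s = {"a": [sample("a")], "b": [sample("b"), sample("b", -24.0)]}
        with pytest.warns(UserWarning, match="excluded"):
            out, report = pool_taxa(s, [(("a", "b"), "genus")])
        assert "a" in out  # untouched, not silently dropped

    def test_null_pooling_rate_matches_independence(self):
        """Under equal means the pool-unless-distinct rule fires with
        probability (1 − α)² (two independent isotopes)."""
        rng = np.random.default_rng(5)
        alpha, n_rep, pooled = 0.05, 1000, 0
        for _ in range(n_rep):
            s = {
                "a": [sample("a", c, n) for c, n in zip(
                    rng.normal(-25, 1, 10), rng.normal(5, 1, 10))],
                "b": [sample("b", c, n) for c, n in zip(
                    rng.normal(-25, 1, 10), rng.normal(5, 1, 10))],
            }
            _, rep = pool_taxa(s, [(("a", "b"), "g")], alpha=alpha)
            pooled += rep.decisions[0].pooled
        expected = (1 - alpha) ** 2
        se = np.sqrt(expected * (1 - expected) / n_rep)
        assert abs(pooled / n_rep - expected) < 4 * se

    def test_decision_matches_independent_welch_t(self):
        """p-values agree with a from-scratch Welch t-statistic."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            x = rng.normal(-25, 1, 12)
            y = rng.normal(-25 + rng.normal(0, 1), 1, 8)
            s = {
                "a": [sample("a", c, 5.0) for c in x],
                "b": [sample("b", c, 5.0) for c in y],
            }
            _, rep = pool_taxa(s, [(("a", "b"), "g")])
            vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
            t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
            df = (vx + vy) ** 2 / (
                vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)
            )
            p_manual = 2 * stats.t.sf(abs(t), df)
            assert rep.decisions[0].p_d13C == pytest.approx(p_manual, abs=1e-10)


class TestUnknownProducer:
    def zoop(self):
        return [
            sample("zoop", -28.0, 8.0),
            sample("zoop", -28.5, 8.5),
            sample("zoop", -27.5, 7.5),
        ]

    def test_one_trophic_step_subtraction(self):
        node = make_unknown_producer(self.zoop(), zooplankton_tef=(0.4, 2.5))
        assert node.mean_d15N == pytest.approx(8.0 - 2.5)
        assert node.mean_d13C == pytest.approx(-28.0 - 0.4)
        assert node.synthetic

    def test_zero_tef_copies_signature(self):
        node = make_unknown_producer(self.zoop(), zooplankton_tef=(0.0, 0.0))
        assert node.mean_d13C == pytest.approx(-28.0)
        assert node.mean_d15N == pytest.approx(8.0)

    def test_absent_zooplankton_raises(self):
        with pytest.raises(ValueError, match="zooplankton"):
            make_unknown_producer([])


def test_default_tef_table_groups():
    assert set(DEFAULT_TEF_TABLE) == {"fish", "invertebrate", "primary_consumer"}
    assert DEFAULT_TEF_TABLE["fish"][0] == pytest.approx(3.4)
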