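import math

import numpy as np
import pandas as pd
import pytest

from ppibayes import (
    BinningConfig,
    build_network,
    composite_lr,
    fit_likelihood_model,
    posterior_odds,
    score_table,
)
from ppibayes.bayes import ChannelLR, LikelihoodModel
from ppibayes.gold_standards import GoldStandard


def _table(rows: dict[tuple[str, str], dict]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(sorted(rows), names=["protein_a", "protein_b"])
    cols = ["rho", "ddi_hit", "interolog_count", "ssbp_size"]
    data = [[rows[p].get(c, np.nan) for c in cols] for p in sorted(rows)]
    return pd.DataFrame(data, index=idx, columns=cols, dtype=float)


def _manual_model(channel_lrs: dict[str, float]) -> LikelihoodModel:
    """One-bin-per-channel model whose LR is fixed, for algebraic tests."""
    channels = {
        name: ChannelLR(
            name=name,
            edges=np.array([-np.inf, np.inf]),
            count_gsp=np.array([1]),
            count_gsn=np.array([1]),
            lr=np.array([lr]),
        )
        for name, lr in channel_lrs.items()
    }
    return LikelihoodModel(channels=channels)


class TestFitLikelihoodModel:
    def test_binary_channel_ratio_of_proportions(self):
        # ddi present in 3/4 GSP pairs and 1/4 GSN pairs, no smoothing
        gsp = {(f"a{i}", f"b{i}") for i in range(4)}
        gsn = {(f"c{i}", f"d{i}") for i in range(4)}
        rows = {}
        for i, p in enumerate(sorted(gsp)):
            rows[p] = {"ddi_hit": 1.0 if i < 3 else 0.0}
        for i, p in enumerate(sorted(gsn)):
            rows[p] = {"ddi_hit": 1.0 if i < 1 else 0.0}
        model = fit_likelihood_model(
            _table(rows), GoldStandard(gsp=gsp, gsn=gsn), pseudocount=0.0
        )
        ch = model.channels["ddi_hit"]
        present_bin = ch.bin_index(1.0)
        assert ch.lr[present_bin] == pytest.approx(3.0)
        absent_bin = ch.bin_index(0.0)
        assert ch.lr[absent_bin] == pytest.approx((1 / 4) / (3 / 4))

    def test_identical_distributions_give_unit_lr(self):
        gsp = {(f"a{i}", f"b{i}") for i in range(4)}
        gsn = {(f"c{i}", f"d{i}") for i in range(4)}
        rows = {}
        for group in (sorted(gsp), sorted(gsn)):
            for i, p in enumerate(group):
                rows[p] = {"ddi_hit": 1.0 if i % 2 == 0 else 0.0}
        model = fit_likelihood_model(
            _table(rows), GoldStandard(gsp=gsp, gsn=gsn), pseudocount=0.0
        )
        assert np.allclose(model.channels["ddi_hit"].lr, 1.0)

    def test_bin_counts_match_independent_recount(self, small_result):
        model = small_result.model
        gold = small_result.gold
        evidence = small_result.evidence
        ch = model.channels["rho"]
        for side, counts in (("gsp", ch.count_gsp), ("gsn", ch.count_gsn)):
            pairs = sorted(getattr(gold, side) & set(evidence.index))
            values = evidence.loc[pairs, "rho"].dropna().to_numpy()
            recount = np.bincount(
                np.searchsorted(ch.edges, values, side="right") - 1,
                minlength=ch.n_bins,
            )
            assert (recount == counts).all()
        # and the LR formula holds bin by bin
        k = model.pseudocount
        n_p, n_n = ch.count_gsp.sum(), ch.count_gsn.sum()
        expected = ((ch.count_gsp + k) / (n_p + k * ch.n_bins)) / (
            (ch.count_gsn + k) / (n_n + k * ch.n_bins)
        )
        assert np.allclose(ch.lr, expected)

    def test_scaling_both_gold_sides_leaves_lr_unchanged(self):
        def fit(copies: int):
            gsp = {(f"a{i}", f"b{i}") for i in range(2 * copies)}
            gsn = {(f"c{i}", f"d{i}") for i in range(2 * copies)}
            rows = {}
            for group in (sorted(gsp), sorted(gsn)):
                for i, p in enumerate(group):
                    rows[p] = {"ddi_hit": float(i % 2)}
            # make GSP twice as often 'present' as GSN
            for i, p in enumerate(sorted(gsp)):
                rows[p] = {"ddi_hit": 1.0 if i < copies else 0.0}
            for i, p in enumerate(sorted(gsn)):
                rows[p] = {"ddi_hit": 1.0 if i < copies // 2 else 0.0}
            return fit_likelihood_model(
                _table(rows), GoldStandard(gsp=gsp, gsn=gsn), pseudocount=0.0
            )

        lr2 = fit(2).channels["ddi_hit"].lr
        lr8 = fit(8).channels["ddi_hit"].lr
        assert np.allclose(lr2, lr8)

    def test_empty_gold_side_raises(self):
        table = _table({("a", "b"): {"ddi_hit": 1.0}})
        with pytest.raises(ValueError, match="GSN"):
            fit_likelihood_model(table, GoldStandard(gsp={("a", "b")}, gsn=set()))

    def test_fully_missing_channel_dropped_with_warning(self, caplog):
        gsp = {("a1", "b1"), ("a2", "b2")}
        gsn = {("c1", "d1"), ("c2", "d2")}
        rows = {p: {"ddi_hit": 1.0} for p in gsp}
        rows.update({p: {"ddi_hit": 0.0} for p in gsn})
        with caplog.at_level("WARNING"):
            model = fit_likelihood_model(
                _table(rows), GoldStandard(gsp=gsp, gsn=gsn)
            )
        assert set(model.channels) == {"ddi_hit"}
        assert "dropped" in caplog.text

    def test_smoothing_keeps_all_lrs_finite_positive(self, small_result):
        for ch in small_result.model.channels.values():
            assert np.all(np.isfinite(ch.lr))
            assert np.all(ch.lr > 0)

    def test_json_round_trip(self, small_result, tmp_path):
        model = small_result.model
        model.to_json(tmp_path / "m.json")
        back = LikelihoodModel.from_json(tmp_path / "m.json")
        assert set(back.channels) == set(model.channels)
        for name, ch in model.channels.items():
            assert np.allclose(back.channels[name].edges, ch.edges)
            assert np.allclose(back.channels[name].lr, ch.lr)
        assert back.training_gsp == model.training_gsp


class TestCompositeLr:
    def test_product_of_channel_lrs(self):
        model = _manual_model({"rho": 2.0, "ddi_hit": 3.0, "interolog_count": 5.0})
        value = composite_lr(
            {"rho": 0.5, "ddi_hit": 1.0, "interolog_count": 2.0}, model
        )
        assert value == pytest.approx(30.0, rel=1e-12)

    def test_all_missing_gives_unit_lr(self):
        model = _manual_model({"rho": 2.0, "ddi_hit": 3.0})
        assert composite_lr({"rho": float("nan"), "ddi_hit": None}, model) == 1.0

    def test_score_table_agrees_with_scalar_path(self, small_result, rng):
        evidence = small_result.evidence
        model = small_result.model
        pick = rng.choice(len(evidence), size=100, replace=False)
        sub = evidence.iloc[sorted(pick)]
        vec = score_table(sub, model)
        for pair, row in sub.iterrows():
            assert vec[pair] == pytest.approx(
                composite_lr(row.to_dict(), model), rel=1e-12
            )

    def test_out_of_range_value_clamps_to_edge_bin(self):
        ch = ChannelLR(
            name="interolog_count",
            edges=np.array([-np.inf, 1.0, np.inf]),
            count_gsp=np.array([1, 1]),
            count_gsn=np.array([1, 1]),
            lr=np.array([0.5, 4.0]),
        )
        model = LikelihoodModel(channels={"interolog_count": ch})
        assert composite_lr({"interolog_count": 99.0}, model) == 4.0
        assert composite_lr({"interolog_count": -99.0}, model) == 0.5


class TestPosteriorOdds:
    def test_prior_times_lr(self):
        assert posterior_odds(117.0, 0.001) == pytest.approx(0.117)

    def test_unit_lr_preserves_prior(self):
        assert posterior_odds(1.0, 0.042) == 0.042

    def test_log_additivity(self):
        for lr, prior in [(2.5, 0.3), (117.0, 0.001), (1e-4, 7.0)]:
            assert math.log(posterior_odds(lr, prior)) == pytest.approx(
                math.log(prior) + math.log(lr), abs=1e-12
            )

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            posterior_odds(0.0, 1.0)
        with pytest.raises(ValueError):
            posterior_odds(1.0, -2.0)


class TestBuildNetwork:
    def test_vacuous_threshold_gives_empty_network(self, small_result, caplog):
        with caplog.at_level("WARNING"):
            net = build_network(
                set(small_result.evidence.index),
                small_result.evidence,
                small_result.model,
                lr_cutoff=1e30,
                gsp=set(),
            )
        assert net.edges == {}

    def test_cutoff_below_minimum_keeps_all_candidates(self, small_result):
        candidates = sorted(small_result.evidence.index)[:200]
        net = build_network(
            candidates,
            small_result.evidence,
            small_result.model,
            lr_cutoff=1e-30,
            gsp=set(),
        )
        assert set(net.edges) == set(candidates)

    def test_surviving_edges_match_bruteforce_filter(self, small_result):
        evidence = small_result.evidence
        model = small_result.model
        gsp = small_result.gold.gsp
        cutoff = 5.0
        candidates = set(evidence.index) - gsp
        net = build_network(candidates, evidence, model, lr_cutoff=cutoff, gsp=gsp)
        scores = score_table(evidence, model)
        brute_predicted = {
            p for p in candidates if scores[p] >= cutoff
        }
        predicted = {p for p, v in net.provenance.items() if v == "prediction"}
        assert predicted == brute_predicted
        gold = {p for p, v in net.provenance.items() if v == "gold_positive"}
        assert gold == gsp

    def test_raising_cutoff_never_adds_an_edge(self, small_result):
        evidence = small_result.evidence
        model = small_result.model
        gsp = small_result.gold.gsp
        candidates = set(evidence.index) - gsp
        previous = None
        for cutoff in (0.5, 1.0, 2.0, 5.0, 20.0, 100.0):
            net = build_network(
                candidates, evidence, model, lr_cutoff=cutoff, gsp=gsp
            )
            predicted = {p for p, v in net.provenance.items() if v == "prediction"}
            gold = {p for p, v in net.provenance.items() if v == "gold_positive"}
            assert gold == gsp  # gold portion is cutoff-independent
            if previous is not None:
                assert predicted <= previous
            previous = predicted

    def test_true_pairs_score_higher_than_non_pairs(self, small_result):
        """Planted interactions should carry larger composite LRs than
        random non-interacting pairs on strong-signal synthetic data."""
        evidence = small_result.evidence
        scores = score_table(evidence, small_result.model)
        truth = small_result.universe.true_edges
        in_truth = scores.index.isin(list(truth))
        assert scores[in_truth].mean() > 3 * scores[~in_truth].mean()
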