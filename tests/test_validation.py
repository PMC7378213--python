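import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from varpanel.synthetic_data import generate_expression
from varpanel.validation import (
    DISEASE,
    HEALTHY,
    ExpressionDataset,
    cross_dataset_auc,
    deg_panel,
    enrichment_rank,
    panel_overlap_check,
    read_expression_tsv,
    read_gmt,
)


def dataset_from_arrays(values, labels, genes=None, dataset_id="DS"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=genes, columns=samples),
        labels=pd.Series(labels, index=samples),
    )


def auc_pairwise_oracle(scores, y):
    """P(random disease sample outranks random healthy sample), ties 0.5."""
    pos = [s for s, yi in zip(scores, y) if yi == 1]
    neg = [s for s, yi in zip(scores, y) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestCrossDatasetAuc:
    def test_round_count_is_n_times_n_minus_1(self):
        datasets = generate_expression(n_datasets=3, n_per_class=5, seed=1)
        panel = datasets[0].genes[:10]
        report = cross_dataset_auc(panel, datasets, n_trees=20, seed=1)
        assert len(report.rounds) == 6

    def test_strong_signal_high_auc(self):
        datasets = generate_expression(
            n_datasets=2, effect_size=3.0, noise_sd=1.0, n_per_class=30, seed=2
        )
        panel = [g for g in datasets[0].genes][:20]
        report = cross_dataset_auc(panel, datasets, n_trees=100, seed=2)
        assert report.mean_auc >= 0.95

    def test_errors(self):
        datasets = generate_expression(n_datasets=1, n_per_class=3, seed=3)
        with pytest.raises(ValueError):
            cross_dataset_auc(datasets[0].genes[:5], datasets, seed=0)
        with pytest.raises(ValueError):
            cross_dataset_auc([], generate_expression(n_datasets=2, n_per_class=3, seed=3), seed=0)

    def test_no_overlap_round_skipped(self):
        datasets = generate_expression(n_datasets=2, n_per_class=4, seed=4)
        other = dataset_from_arrays(
            np.random.default_rng(0).normal(size=(4, 8)),
            [HEALTHY] * 4 + [DISEASE] * 4,
            genes=["x1", "x2", "x3", "x4"],
            dataset_id="OTHER",
        )
        panel = datasets[0].genes[:5]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cross_dataset_auc(panel, [datasets[0], other], n_trees=10, seed=0)
        assert len(report.skipped_rounds) == 2 and len(report.rounds) == 0

    def test_auc_matches_exhaustive_pairwise_oracle(self):
        """The rank-statistic AUC equals the probability that a random
        disease sample outranks a random healthy one."""
        rng = np.random.default_rng(5)
        y = np.array([0] * 60 + [1] * 60)
        scores = np.round(rng.normal(size=120) + 0.8 * y, 1)  # rounding forces ties
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, scores) == pytest.approx(auc_pairwise_oracle(scores, y))

    def test_deterministic_given_seed(self):
        datasets = generate_expression(n_datasets=2, n_per_class=8, seed=6)
        panel = datasets[0].genes[:10]
        r1 = cross_dataset_auc(panel, datasets, n_trees=50, seed=9)
        r2 = cross_dataset_auc(panel, datasets, n_trees=50, seed=9)
        assert r1.rounds == r2.rounds


class TestDegPanel:
    def build(self, disease_shift, n=20, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        base = np.full((len(disease_shift), 2 * n), 2.0)
        base[:, n:] += np.asarray(disease_shift)[:, None]
        base += rng.normal(0, noise, base.shape)
        return dataset_from_arrays(base, [HEALTHY] * n + [DISEASE] * n)

    def test_identical_class_means_excluded(self):
        ds = self.build([0.0, 6.0])
        assert "g0" not in deg_panel(ds)

    def test_fold_change_gate(self):
        # 2.3x change (log2FC ~ 1.2) is significant but below the 1.5 gate
        ds = self.build([2.6, 6.0])
        panel = deg_panel(ds)
        assert "g0" not in panel and "g1" in panel

    def test_planted_fourfold_gene_included(self):
        # 4-fold difference, low noise, 20 vs 20 samples
        ds = self.build([6.0, 0.0])
        assert "g0" in deg_panel(ds)

    def test_small_class_rejected(self):
        ds = dataset_from_arrays(
            [[1.0, 2.0, 3.0]], [HEALTHY, DISEASE, DISEASE]
        )
        with pytest.raises(ValueError):
            deg_panel(ds)

    def test_type_one_error_controlled_without_signal(self):
        included = total = 0
        for rep in range(20):
            (ds,) = generate_expression(
                n_datasets=1, effect_size=0.0, n_per_class=15, seed=100 + rep
            )
            included += len(deg_panel(ds))
            total += len(ds.genes)
        assert included / total <= 0.05 + 0.02


def hypergeom_tail_oracle(k, M, n, N):
    """P(X >= k) by exact combinatorial enumeration."""
    denom = math.comb(M, N)
    total = 0
    for x in range(k, min(n, N) + 1):
        total += math.comb(n, x) * math.comb(M - n, N - x)
    return total / denom


class TestEnrichmentRank:
    UNIVERSE = {f"g{i}" for i in range(10)}

    def test_zero_overlap_p_is_one(self):
        ranked, _ = enrichment_rank(
            ["g0", "g1"], {"pw": {"g5", "g6"}}, self.UNIVERSE
        )
        assert ranked[0][2] == pytest.approx(1.0)

    def test_exact_combinatorial_value(self):
        # universe 10, panel 5, pathway 2, overlap 2 -> C(5,2)/C(10,2) = 10/45
        panel = [f"g{i}" for i in range(5)]
        ranked, _ = enrichment_rank(panel, {"pw": {"g0", "g1"}}, self.UNIVERSE)
        assert ranked[0][2] == pytest.approx(10 / 45, abs=1e-12)

    def test_pathway_equal_to_panel_ranks_first(self):
        panel = ["g0", "g1", "g2"]
        pathways = {
            "target": set(panel),
            "other": {"g7", "g8", "g9"},
            "partial": {"g0", "g7"},
        }
        ranked, rank = enrichment_rank(panel, pathways, self.UNIVERSE, target_pathway="target")
        assert rank == 1 and ranked[0][0] == "target"

    def test_panel_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enrichment_rank(["nope"], {"pw": {"g0"}}, self.UNIVERSE)

    def test_ties_broken_by_overlap_then_name(self):
        panel = list(self.UNIVERSE)
        # every pathway has p = 1 characteristics? use full-panel: all p equal
        pathways = {"b": {"g0"}, "a": {"g0"}}
        ranked, _ = enrichment_rank(panel, pathways, self.UNIVERSE)
        assert [r[0] for r in ranked] == ["a", "b"]

    def test_matches_enumeration_on_small_instances(self):
        universe = {f"g{i}" for i in range(12)}
        panel = [f"g{i}" for i in range(4)]
        for size in range(1, 12):
            pw = {f"g{i}" for i in range(size)}
            ranked, _ = enrichment_rank(panel, {"pw": pw}, universe)
            overlap = len(set(panel) & pw)
            assert ranked[0][2] == pytest.approx(
                hypergeom_tail_oracle(overlap, 12, 4, size), abs=1e-12
            )


def test_hypergeom_pmf_sums_to_one_and_tail_monotone():
    M, n, N = 25, 9, 11
    total = sum(stats.hypergeom.pmf(x, M, n, N) for x in range(0, min(n, N) + 1))
    assert total == pytest.approx(1.0, abs=1e-12)
    tails = [float(stats.hypergeom.sf(k - 1, M, n, N)) for k in range(0, min(n, N) + 2)]
    assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))


class TestPanelOverlap:
    def make_ds(self, genes, dataset_id="DS"):
        return dataset_from_arrays(
            np.ones((len(genes), 4)), [HEALTHY, HEALTHY, DISEASE, DISEASE],
            genes=genes, dataset_id=dataset_id,
        )

    def test_full_overlap(self):
        per, avg = panel_overlap_check(["g0", "g1"], [self.make_ds(["g0", "g1", "g2"])])
        assert per == {"DS": 100.0} and avg == 100.0

    def test_half_overlap_warns(self):
        with pytest.warns(UserWarning, match="below 80"):
            _, avg = panel_overlap_check(["g0", "zz"], [self.make_ds(["g0", "g1"])])
        assert avg == 50.0

    def test_average_at_bar_no_warning(self):
        d90 = self.make_ds([f"g{i}" for i in range(9)] + ["zz"], dataset_id="D90")
        d70 = self.make_ds([f"g{i}" for i in range(7)] + ["z1", "z2", "z3"], dataset_id="D70")
        panel = [f"g{i}" for i in range(10)]
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            per, avg = panel_overlap_check(panel, [d90, d70])
        assert avg == pytest.approx(80.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            panel_overlap_check([], [self.make_ds(["g0"])])


def test_expression_tsv_round_trip(tmp_path):
    (ds,) = generate_expression(n_datasets=1, n_per_class=3, seed=8)
    ds.values.to_csv(tmp_path / "m.tsv", sep="\t")
    ds.labels.to_csv(tmp_path / "l.tsv", sep="\t", header=False)
    back = read_expression_tsv(tmp_path / "m.tsv", tmp_path / "l.tsv", dataset_id="DS0")
    assert np.allclose(back.values.to_numpy(), ds.values.to_numpy())
    assert list(back.labels) == list(ds.labels)


def test_gmt_reader(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("pw1\tdesc\tg1\tg2\npw2\tdesc\tg3\n")
    sets = read_gmt(p)
    assert sets == {"pw1": {"g1", "g2"}, "pw2": {"g3"}}
    (tmp_path / "bad.gmt").write_text("pw1\tonlydesc\n")
    with pytest.raises(ValueError):
        read_gmt(tmp_path / "bad.gmt")
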