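import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tpll_subtyper import network as net
from tpll_subtyper.network import (
    CandidateLink,
    GeneModel,
    NetworkEnsemble,
    NetworkRun,
)


def _expr_frame(arr, genes, samples):
    return pd.DataFrame(np.asarray(arr, dtype=float), index=genes,
                        columns=samples)


class TestCovarianceTest:
    def test_planted_predictor_enters_first_with_tiny_p(self, rng):
        n, p = 50, 21
        X = rng.normal(size=(n, p))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.1, size=n)
        genes = [f"G{i}" for i in range(p)] + ["TARGET"]
        expr = _expr_frame(np.vstack([X.T, y]), genes,
                           [f"S{i}" for i in range(n)])
        models = net.infer_network(expr, None, train_ids=list(expr.columns),
                                   link_q=0.01, seed=0)
        m = models["TARGET"]
        assert m.candidates[0].predictor == "G0"
        assert m.candidates[0].p < 1e-4
        retained = {c.predictor: c.beta for c in m.retained_predictors}
        assert "G0" in retained
        assert retained["G0"] == pytest.approx(3.0, abs=0.1)

    def test_null_first_knot_statistic_is_exp1(self, rng):
        """Under a pure-noise response the first covariance-test statistic
        (on the known-σ² scale) follows Exp(1); the limit is asymptotic in
        the number of predictors, so a wide design is used."""
        n, p, sims = 100, 500, 1000
        stats = []
        for _ in range(sims):
            X = rng.normal(size=(n, p))
            X = (X - X.mean(axis=0)) / X.std(axis=0)
            y = rng.normal(size=n)
            y = y - y.mean()
            events = net.covariance_test_path(X, y, max_steps=2)
            stats.append(events[0][1])
        # centering y costs one df: Var(centered y) = (n-1)/n, so rescale
        # back to the unit-σ² statistic
        stats = np.asarray(stats) * n / (n - 1)
        ks = sps.kstest(stats, "expon")
        assert ks.pvalue > 0.01

    def test_cis_only_response_keeps_cn_link(self, rng):
        n = 40
        cn_vals = rng.normal(size=n)
        decoys = rng.normal(size=(8, n))
        genes = ["TARGET"] + [f"D{i}" for i in range(8)]
        samples = [f"S{i}" for i in range(n)]
        expr = _expr_frame(np.vstack([cn_vals, decoys]), genes, samples)
        cn = _expr_frame(np.vstack([cn_vals, np.zeros((8, n))]), genes, samples)
        models = net.infer_network(expr, cn, train_ids=samples, seed=1)
        m = models["TARGET"]
        assert m.cn_coefficient == pytest.approx(1.0, abs=0.05)
        assert not m.retained_predictors  # no expression predictors kept


def _fabricated_ensemble(support_map, n_runs=100, sign=1.0):
    """Build an ensemble whose runs retain each undirected link A-B in
    exactly support_map[(A,B)] runs."""
    genes = sorted({g for pair in support_map for g in pair})
    runs = []
    for r in range(n_runs):
        models = {g: GeneModel(target=g) for g in genes}
        for (a, b), s in support_map.items():
            if r < s:
                models[b].candidates.append(CandidateLink(
                    predictor=a, entry_order=1, T=10.0, p=1e-6,
                    beta=sign, q=1e-5, retained=True))
        runs.append(NetworkRun(train_ids=[], test_ids=[], models=models,
                               seed=r))
    return NetworkEnsemble(runs=runs, gene_ids=genes, link_q=0.01, seed=0)


class TestConsensusAndModules:
    def test_toy_triangle_kept_low_support_dropped(self):
        ens = _fabricated_ensemble({("A", "B"): 80, ("B", "C"): 76,
                                    ("C", "A"): 90, ("D", "E"): 74})
        out = net.consensus_and_modules(ens, support_min=75)
        pairs = {frozenset((r.predictor, r.target))
                 for r in out["links"].itertuples()}
        assert pairs == {frozenset("AB"), frozenset("BC"), frozenset("CA")}
        assert out["modules"] == [["A", "B", "C"]]

    def test_chain_pruned_to_nothing(self):
        ens = _fabricated_ensemble({("A", "B"): 80, ("B", "C"): 80})
        out = net.consensus_and_modules(ens, support_min=75)
        assert len(out["links"]) == 2
        assert out["modules"] == []

    def test_empty_ensemble_links(self):
        ens = _fabricated_ensemble({})
        out = net.consensus_and_modules(ens, support_min=75)
        assert len(out["links"]) == 0
        assert out["modules"] == []

    def test_consensus_shrinks_with_support_threshold(self):
        support = {("A", "B"): 90, ("B", "C"): 80, ("C", "D"): 70,
                   ("D", "E"): 60}
        ens = _fabricated_ensemble(support)
        sizes = [len(net.consensus_and_modules(ens, support_min=s)["links"])
                 for s in (50, 65, 75, 85, 95)]
        assert sizes == sorted(sizes, reverse=True)

    def test_negative_links_retained_with_sign(self):
        ens = _fabricated_ensemble({("A", "B"): 90}, sign=-2.0)
        out = net.consensus_and_modules(ens, support_min=75)
        assert out["links"].iloc[0]["sign"] == -1


class TestRewiring:
    def test_degree_preservation(self, rng):
        genes = [f"G{i}" for i in range(12)]
        models = {g: GeneModel(target=g) for g in genes}
        edges = [("G0", "G1"), ("G0", "G2"), ("G0", "G3"), ("G4", "G5"),
                 ("G4", "G6"), ("G7", "G8"), ("G9", "G10"), ("G2", "G11")]
        for p, t in edges:
            models[t].candidates.append(CandidateLink(
                predictor=p, entry_order=1, T=5.0, p=1e-4, beta=1.0,
                retained=True))
        run = NetworkRun(train_ids=[], test_ids=[], models=models, seed=0)
        null = net._rewire_run(run, rng)
        out_deg = lambda ms: pd.Series(
            [c.predictor for m in ms.values() for c in m.retained_predictors]
        ).value_counts().to_dict()
        in_deg = lambda ms: {t: len(m.retained_predictors)
                             for t, m in ms.items()}
        assert out_deg(null) == out_deg(models)
        assert in_deg(null) == in_deg(models)


class TestAnnotateModules:
    def test_directions(self):
        table = pd.DataFrame({
            "log2fc": [2.0, -1.0, 0.5],
            "q": [0.01, 0.2, 0.3],
        }, index=["A", "B", "C"])
        res = type("R", (), {"table": table})()
        out = net.annotate_module_expression([["A", "B", "C"]],
                                             {"SG1": res})
        row = out.set_index("gene")
        assert row.loc["A", "SG1"] == "+"
        assert row.loc["B", "SG1"] == "="
        assert row.loc["C", "SG1"] == "="

    def test_missing_gene_flagged_unchanged(self):
        table = pd.DataFrame({"log2fc": [1.0], "q": [0.001]}, index=["A"])
        res = type("R", (), {"table": table})()
        out = net.annotate_module_expression([["A", "ZZ"]], {"SG2": res})
        row = out.set_index("gene")
        assert row.loc["ZZ", "SG2"] == "="
        assert row.loc["ZZ", "flagged"]


class TestEnsemble:
    def test_train_test_split_sizes(self, rng):
        genes = [f"G{i}" for i in range(12)]
        samples = [f"S{i}" for i in range(53)]
        expr = _expr_frame(rng.normal(size=(12, 53)), genes, samples)
        ens = net.infer_ensemble(expr, None, n_runs=2, seed=0, max_steps=3)
        for run in ens.runs:
            assert len(run.train_ids) == 35
            assert len(run.test_ids) == 18

    def test_same_seed_reproduces_ensemble(self, rng):
        genes = [f"G{i}" for i in range(8)]
        samples = [f"S{i}" for i in range(24)]
        arr = rng.normal(size=(8, 24))
        a = net.infer_ensemble(_expr_frame(arr, genes, samples), None,
                               n_runs=2, seed=42, max_steps=3)
        b = net.infer_ensemble(_expr_frame(arr, genes, samples), None,
                               n_runs=2, seed=42, max_steps=3)
        for ra, rb in zip(a.runs, b.runs):
            assert ra.train_ids == rb.train_ids
            for g in genes:
                ca = [(c.predictor, c.p) for c in ra.models[g].candidates]
                cb = [(c.predictor, c.p) for c in rb.models[g].candidates]
                assert ca == cb

    def test_single_run_ensemble_supported_downstream(self, rng):
        genes = [f"G{i}" for i in range(8)]
        samples = [f"S{i}" for i in range(24)]
        expr = _expr_frame(rng.normal(size=(8, 24)), genes, samples)
        ens = net.infer_ensemble(expr, None, n_runs=1, seed=3, max_steps=3)
        out = net.consensus_and_modules(ens, support_min=1)
        assert isinstance(out["links"], pd.DataFrame)
        quality = net.prediction_quality(ens, expr, None)
        assert len(quality) == len(genes)
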