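import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efdb.errors import EfdbError, SeriesError
from efdb.query import (
    QueryProfile,
    build_query_from_replicates,
    correlate,
    fisher_score,
    read_query_tsv,
    score_series_groups,
    search_database,
    write_query_tsv,
)
from efdb.store import FoldDatabase, write_database

from conftest import make_series


def pearson_oracle(x, y):
    """Textbook sum formula, independent of numpy's implementation."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


class TestBuildQuery:
    def _series(self, rows):
        return make_series(rows, sample_ids=["t0", "t1", "t2", "c0", "c1", "c2"])

    def test_identical_groups_empty(self):
        series = self._series(np.tile([[5.0]], (4, 6)))
        query = build_query_from_replicates(["t0", "t1", "t2"],
                                            ["c0", "c1", "c2"], series)
        assert len(query) == 0

    def test_filter_then_truncate_matches_brute_force(self):
        rng = np.random.default_rng(5)
        rows = []
        # 4 strongly separated genes with graded effect + 2 null genes
        for mult in (8.0, 4.0, 2.7, 1.8):
            base = rng.uniform(50, 100)
            rows.append([base * mult * (1 + 0.01 * rng.standard_normal())
                         for _ in range(3)]
                        + [base * (1 + 0.01 * rng.standard_normal())
                           for _ in range(3)])
        for _ in range(2):
            base = rng.uniform(50, 100)
            rows.append([base * (1 + 0.01 * rng.standard_normal())
                         for _ in range(6)])
        series = self._series(np.array(rows))
        treat, ctrl = ["t0", "t1", "t2"], ["c0", "c1", "c2"]
        from efdb.ef import compute_pooled_fold_profile

        pooled = compute_pooled_fold_profile(treat, ctrl, series)
        passing = [g for g, p in pooled.p_values.items() if p < 0.05]
        assert len(passing) == 4  # sanity of the fixture
        expected = sorted(passing, key=lambda g: -abs(pooled.folds[g]))[:3]
        query = build_query_from_replicates(treat, ctrl, series,
                                            alpha=0.05, max_genes=3)
        assert sorted(query.entries) == sorted(expected)

    def test_max_genes_larger_than_passing_set(self):
        series = self._series(
            np.array([[80.0, 82.0, 81.0, 20.0, 21.0, 19.0]]))
        query = build_query_from_replicates(
            ["t0", "t1", "t2"], ["c0", "c1", "c2"], series, max_genes=500)
        assert len(query) == 1

    def test_too_few_samples(self):
        series = make_series([[1.0, 2.0, 3.0]])
        with pytest.raises(SeriesError):
            build_query_from_replicates(["gsm0"], ["gsm1", "gsm2"], series)


class TestCorrelate:
    def test_self_match(self):
        query = QueryProfile("q", {f"g{i}": (v, 0.01) for i, v in
                                   enumerate([1.0, 0.5, -1.0, -0.5, 0.2])})
        r, n = correlate(query, query.folds())
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_negated_target(self):
        query = QueryProfile("q", {f"g{i}": (v, 0.01) for i, v in
                                   enumerate([1.0, 0.5, -1.0, -0.5, 0.2])})
        r, _ = correlate(query, {g: -v for g, v in query.folds().items()})
        assert r == pytest.approx(-1.0)

    def test_textbook_oracle(self):
        query = QueryProfile("q", {
            "a": (1.0, 0.01), "b": (0.5, 0.01),
            "c": (-1.0, 0.01), "d": (-0.5, 0.01),
        })
        target = {"a": 0.8, "b": 0.1, "c": -0.9, "d": 0.2}
        r, n = correlate(query, target, min_shared_genes=4)
        assert n == 4
        assert r == pytest.approx(
            pearson_oracle([1.0, 0.5, -1.0, -0.5], [0.8, 0.1, -0.9, 0.2]),
            abs=1e-12)

    def test_min_shared_floor(self):
        query = QueryProfile("q", {"a": (1.0, 0.01), "b": (-1.0, 0.01)})
        assert correlate(query, {"a": 1.0, "b": -1.0},
                         min_shared_genes=5) is None

    def test_zero_variance_null(self):
        query = QueryProfile("q", {f"g{i}": (1.0, 0.01) for i in range(6)})
        target = {f"g{i}": 0.3 for i in range(6)}
        assert correlate(query, target) is None

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            x = rng.uniform(-2, 2, size=n)
            y = rng.uniform(-2, 2, size=n)
            query = QueryProfile("q", {f"g{i}": (float(x[i]), 0.01)
                                       for i in range(n)})
            r, _ = correlate(query, {f"g{i}": float(y[i]) for i in range(n)})
            assert r == pytest.approx(pearson_oracle(x.tolist(), y.tolist()),
                                      abs=1e-12)


class TestFisherScore:
    def test_zero_r(self):
        assert fisher_score(0.0, 10) == 0.0

    def test_closed_form_small(self):
        # sqrt(1) * 0.5 * ln(3)
        assert fisher_score(0.5, 4) == pytest.approx(0.5493, abs=5e-5)

    def test_closed_form_large(self):
        # sqrt(100) * 0.5 * ln(19) = 5 ln 19
        assert fisher_score(0.9, 103) == pytest.approx(5 * math.log(19),
                                                       abs=1e-12)
        assert fisher_score(0.9, 103) == pytest.approx(14.722, abs=5e-4)

    def test_r_one_clamped_finite(self):
        assert math.isfinite(fisher_score(1.0, 10))
        assert fisher_score(1.0, 10) > fisher_score(0.9999, 10)

    def test_n_below_four_rejected(self):
        with pytest.raises(EfdbError):
            fisher_score(0.5, 3)

    @given(st.floats(min_value=-0.99, max_value=0.99),
           st.integers(min_value=4, max_value=1000))
    def test_antisymmetry(self, r, n):
        assert fisher_score(-r, n) == pytest.approx(-fisher_score(r, n))

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(-0.95, 0.95, 41)
        scores = [fisher_score(float(r), 30) for r in rs]
        assert all(a < b for a, b in zip(scores, scores[1:]))
        ns = range(4, 50)
        scores_n = [fisher_score(0.6, n) for n in ns]
        assert all(a < b for a, b in zip(scores_n, scores_n[1:]))


def _db_with(records, genes, tmp_path, name="db.efdb"):
    db = FoldDatabase("PL", "synthetic", genes)
    for sample_id, series_id, folds in records:
        vector = np.full(len(genes), np.nan)
        for gene, fold in folds.items():
            vector[genes.index(gene)] = fold
        db.records.append((sample_id, series_id, vector))
    path = tmp_path / name
    write_database(db, path)
    return path


class TestSearchDatabase:
    def test_self_and_negated_records(self, tmp_path):
        genes = [f"g{i}" for i in range(8)]
        rng = np.random.default_rng(11)
        folds = {g: float(rng.uniform(-1, 1)) for g in genes}
        records = [
            ("self", "e1", folds),
            ("anti", "e1", {g: -v for g, v in folds.items()}),
            ("noise", "e1", {g: float(rng.uniform(-1, 1)) for g in genes}),
        ]
        path = _db_with(records, genes, tmp_path)
        query = QueryProfile("q", {g: (v, 0.01) for g, v in folds.items()})
        positive, negative = search_database(query, path, top=3)
        assert positive[0].sample_id == "self"
        assert negative[0].sample_id == "anti"
        assert positive[0].r == pytest.approx(1.0)
        assert negative[0].r == pytest.approx(-1.0)

    def test_record_order_invariance(self, tmp_path):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(10)]
        records = [
            (f"s{i}", "e", {g: float(rng.uniform(-1, 1)) for g in genes})
            for i in range(20)
        ]
        query = QueryProfile("q", {g: (float(rng.uniform(-1, 1)), 0.01)
                                   for g in genes})
        p1 = _db_with(records, genes, tmp_path, "a.efdb")
        p2 = _db_with(records[::-1], genes, tmp_path, "b.efdb")
        h1 = search_database(query, p1, top=5)[0]
        h2 = search_database(query, p2, top=5)[0]
        assert [(h.sample_id, h.score) for h in h1] == \
               [(h.sample_id, h.score) for h in h2]

    def test_empty_database(self, tmp_path):
        path = _db_with([], ["g0", "g1"], tmp_path)
        query = QueryProfile("q", {"g0": (1.0, 0.01), "g1": (-1.0, 0.01)})
        positive, negative = search_database(query, path)
        assert positive == [] and negative == []

    def test_antisymmetry_of_negated_database(self, tmp_path):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(12)]
        records = [
            (f"s{i}", "e", {g: float(rng.uniform(-1, 1)) for g in genes})
            for i in range(6)
        ]
        negated = [(s, e, {g: -v for g, v in f.items()})
                   for s, e, f in records]
        query = QueryProfile("q", {g: (float(rng.uniform(-1, 1)), 0.01)
                                   for g in genes})
        pos1, _ = search_database(query, _db_with(records, genes, tmp_path,
                                                  "a.efdb"), top=6)
        _, neg2 = search_database(query, _db_with(negated, genes, tmp_path,
                                                  "b.efdb"), top=6)
        s1 = {h.sample_id: h.score for h in pos1}
        s2 = {h.sample_id: h.score for h in neg2}
        assert s1.keys() == s2.keys()
        for sample in s1:
            assert s2[sample] == pytest.approx(-s1[sample], abs=1e-12)


class TestScoreSeriesGroups:
    def test_pooled_self_consistency(self):
        from efdb.ef import apply_cutoff, rescale_series
        from efdb.simulate import SimulationSpec, simulate_series

        spec = SimulationSpec(n_genes=50, n_probes_per_gene=1, n_treat=3,
                              n_ctrl=3, effect_genes=12, effect_size=4.0,
                              noise_cv=0.1, seed=21)
        series, truth = simulate_series(spec)
        series = apply_cutoff(rescale_series(series), 0.1)
        query = build_query_from_replicates(
            truth["treat_samples"], truth["ctrl_samples"], series,
            max_genes=50)
        groups = {s: "treat" for s in truth["treat_samples"]}
        groups.update({s: "ctrl" for s in truth["ctrl_samples"]})
        result = score_series_groups(query, series, groups)
        r, _ = result["pooled"]
        assert r > 0.95

    def test_single_sample_groups_give_pair_fold(self):
        series = make_series([[30.0, 10.0], [10.0, 30.0]],
                             sample_ids=["t", "c"])
        from efdb.ef import compute_pooled_fold_profile, fold_measure

        pooled = compute_pooled_fold_profile(["t"], ["c"], series)
        assert pooled.folds["p0"] == pytest.approx(fold_measure(30, 10))

    def test_missing_label_rejected(self, small_series):
        query = QueryProfile("q", {"p0": (1.0, 0.01)})
        with pytest.raises(SeriesError):
            score_series_groups(query, small_series, {"gsm0": "treat"})

    def test_null_pooled_r_centred_on_zero(self):
        """Monte-Carlo: random group labels on null data give pooled r
        scattered around 0."""
        from efdb.ef import apply_cutoff, rescale_series
        from efdb.simulate import SimulationSpec, simulate_series

        rng = np.random.default_rng(99)
        rs = []
        query = None
        for seed in range(200):
            spec = SimulationSpec(n_genes=40, n_probes_per_gene=1,
                                  n_treat=3, n_ctrl=3, effect_genes=0,
                                  effect_size=1.0, noise_cv=0.2, seed=seed)
            series, truth = simulate_series(spec)
            series = apply_cutoff(rescale_series(series), 0.1)
            if query is None:
                genes = series.probe_ids
                query = QueryProfile("q", {
                    g: (float(rng.uniform(-1, 1)), 0.01) for g in genes})
            samples = list(series.sample_ids)
            rng.shuffle(samples)
            groups = {s: "treat" for s in samples[:3]}
            groups.update({s: "ctrl" for s in samples[3:]})
            result = score_series_groups(query, series, groups)
            if result["pooled"] is not None:
                rs.append(result["pooled"][0])
        assert len(rs) > 150
        assert abs(np.mean(rs)) < 0.1


def test_query_tsv_round_trip(tmp_path):
    query = QueryProfile("q", {"g1": (1.25, 0.001), "g2": (-0.75, 0.04)})
    path = tmp_path / "query.tsv"
    write_query_tsv(query, path)
    loaded = read_query_tsv(path, alpha=0.05)
    assert loaded.entries == pytest.approx(query.entries)
    # alpha filter applies on read
    strict = read_query_tsv(path, alpha=0.01)
    assert sorted(strict.entries) == ["g1"]
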