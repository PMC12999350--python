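import numpy as np
import pytest

import smibench as sb
from smibench.evaluation import (
    RESOLUTION_GRID,
    cluster_fixed_k,
    cluster_spots,
    clustering_metrics,
    pca_embedding,
    select_hyperparameters,
)
from conftest import random_masked


def _report(truth, pred):
    """Build an AccuracyReport from explicit truth/prediction vectors."""
    n = len(truth)
    ref = np.column_stack([np.asarray(truth, float), np.ones(n)])
    obs = ref.copy()
    obs[:, 0] = np.nan
    mask = np.zeros_like(ref, dtype=bool)
    mask[:, 0] = True
    coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    d = sb.MaskedDataset(
        sb.SpatialMatrix(obs, coords),
        sb.SpatialMatrix(ref, coords),
        mask,
        "MCAR",
        0.5,
        0,
    )
    imputed = ref.copy()
    imputed[:, 0] = pred
    res = sb.ImputationResult(imputed, "test")
    return sb.accuracy_metrics(res, d)


def test_identity_prediction_scores():
    r = _report([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
    assert r.nrmse == 0 and r.rmse == 0 and r.mae == 0
    assert r.pearson == pytest.approx(1.0)
    assert r.cosine == pytest.approx(1.0)


def test_hand_worked_nrmse():
    """truth {1,2,3}, prediction {2,2,2}: population sd = RMSE = sqrt(2/3)."""
    r = _report([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    assert r.rmse == pytest.approx(np.sqrt(2 / 3), rel=1e-12)
    assert r.nrmse == pytest.approx(1.0, rel=1e-12)
    assert r.mae == pytest.approx(2 / 3, rel=1e-12)
    assert r.pearson is None  # constant prediction


def test_metrics_match_brute_force_formulas():
    rng = np.random.default_rng(21)
    t = rng.gamma(2, 3, 100)
    p = t + rng.normal(0, 1, 100)
    p = np.abs(p)
    r = _report(t, p)
    assert r.rmse == pytest.approx(np.sqrt(((t - p) ** 2).sum() / 100), rel=1e-9)
    assert r.nrmse == pytest.approx(
        np.sqrt(((t - p) ** 2).mean()) / np.sqrt(((t - t.mean()) ** 2).mean()),
        rel=1e-9,
    )
    assert r.mae == pytest.approx(np.abs(t - p).mean(), rel=1e-9)
    tc, pc = t - t.mean(), p - p.mean()
    assert r.pearson == pytest.approx(
        (tc * pc).sum() / np.sqrt((tc**2).sum() * (pc**2).sum()), rel=1e-9
    )
    assert r.cosine == pytest.approx(
        (t * p).sum() / np.sqrt((t**2).sum() * (p**2).sum()), rel=1e-9
    )


def test_nrmse_scale_invariance():
    rng = np.random.default_rng(22)
    t = rng.gamma(2, 3, 50)
    p = np.abs(t + rng.normal(0, 1, 50))
    a, b = _report(t, p), _report(7.3 * t, 7.3 * p)
    assert b.nrmse == pytest.approx(a.nrmse, rel=1e-9)
    assert b.rmse == pytest.approx(7.3 * a.rmse, rel=1e-9)
    assert b.mae == pytest.approx(7.3 * a.mae, rel=1e-9)


def test_mask_order_invariance():
    d = random_masked(n=20, p=6, frac=0.3, seed=23)
    res = sb.impute_mean(d)
    r1 = sb.accuracy_metrics(res, d)
    perm = np.random.default_rng(0).permutation(20)
    d2 = sb.MaskedDataset(
        sb.SpatialMatrix(d.observed.intensities[perm], d.observed.coords[perm]),
        sb.SpatialMatrix(d.reference.intensities[perm], d.reference.coords[perm]),
        d.mask[perm],
        d.mechanism,
        d.rate,
        d.seed,
    )
    r2 = sb.accuracy_metrics(sb.impute_mean(d2), d2)
    assert r2.nrmse == pytest.approx(r1.nrmse, rel=1e-12)


def test_degenerate_truth_reported_not_nan():
    r = _report([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    assert r.nrmse is None and r.pearson is None
    assert any("NRMSE" in n for n in r.notes)


def test_empty_mask_errors(tiny_matrix):
    d = sb.mask_mcar(tiny_matrix, 0.0, seed=0)
    res = sb.impute_mean(d)
    with pytest.raises(ValueError):
        sb.accuracy_metrics(res, d)


# ---------------------------------------------------------------------------
# hyperparameter selection
# ---------------------------------------------------------------------------

def _fake_report(nrmse, dataset="d", mech="MCAR", rate=0.3, **hyper):
    return sb.AccuracyReport(
        nrmse, nrmse, nrmse, 0.5, 0.5, 10,
        {"dataset": dataset, "method": "x", "mechanism": mech, "rate": rate,
         "hyperparams": hyper},
    )


def test_select_hyperparameters_cases():
    single = [_fake_report(0.5, k=5)]
    assert select_hyperparameters(single)[("d", "MCAR", 0.3)] is single[0]
    two = [_fake_report(0.5, k=5), _fake_report(0.4, k=10)]
    assert select_hyperparameters(two)[("d", "MCAR", 0.3)].nrmse == 0.4


def test_select_hyperparameters_matches_brute_force_grid():
    rng = np.random.default_rng(24)
    reports = []
    for mech in ("MCAR", "MNAR", "X"):
        for rate in (0.1, 0.2, 0.3, 0.4):
            for k in (5, 10, 15):
                reports.append(_fake_report(float(rng.uniform()), "d", mech, rate, k=k))
    best = select_hyperparameters(reports)
    for key, rep in best.items():
        group = [r for r in reports
                 if (r.context["dataset"], r.context["mechanism"], r.context["rate"]) == key]
        assert rep.nrmse == min(r.nrmse for r in group)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def two_region_fixture():
    spec = sb.SyntheticSpec(
        grid_w=20, grid_h=20, n_metabolites=30, n_regions=2,
        region_effect=4.0, zero_inflation=0.0, seed=31,
    )
    return sb.generate_dataset(spec)


def test_cluster_recovers_separated_regions(two_region_fixture):
    m, labels = two_region_fixture
    emb = pca_embedding(m)
    best = max(
        clustering_metrics(m, cluster_spots(m, "leiden", r, seed=0, embedding=emb),
                           labels, embedding=emb).ari
        for r in RESOLUTION_GRID
    )
    assert best > 0.8


def test_resolution_increases_cluster_count(two_region_fixture):
    m, _ = two_region_fixture
    emb = pca_embedding(m)
    counts = {}
    for r in (0.1, 0.9):
        counts[r] = len(np.unique(cluster_spots(m, "leiden", r, seed=0, embedding=emb)))
    assert counts[0.9] >= counts[0.1]


def test_single_region_low_resolution_few_clusters():
    spec = sb.SyntheticSpec(
        grid_w=15, grid_h=15, n_metabolites=20, n_regions=1,
        region_effect=0.0, smoothness=0.0, zero_inflation=0.0, seed=32,
    )
    m, _ = sb.generate_dataset(spec)
    lab = cluster_spots(m, "leiden", 0.1, seed=0)
    assert len(np.unique(lab)) <= 2


@pytest.mark.parametrize("algo", ["louvain", "leiden", "slm"])
def test_algorithms_run_and_are_deterministic(two_region_fixture, algo):
    m, _ = two_region_fixture
    emb = pca_embedding(m)
    a = cluster_spots(m, algo, 0.4, seed=5, embedding=emb)
    b = cluster_spots(m, algo, 0.4, seed=5, embedding=emb)
    np.testing.assert_array_equal(a, b)
    assert len(a) == m.n_spots


def test_cluster_fixed_k_exact_count(two_region_fixture):
    m, _ = two_region_fixture
    lab = cluster_fixed_k(m, n_clusters=9, seed=0)
    assert len(np.unique(lab)) == 9
    lab2 = cluster_fixed_k(m, n_clusters=9, seed=0)
    np.testing.assert_array_equal(lab, lab2)
    assert (cluster_fixed_k(m, n_clusters=1) == 0).all()
    with pytest.raises(ValueError):
        cluster_fixed_k(m, n_clusters=0)


def test_clustering_metrics_external_agreement(two_region_fixture):
    m, labels = two_region_fixture
    rep = clustering_metrics(m, labels, labels)
    assert rep.nmi == pytest.approx(1.0)
    assert rep.ari == pytest.approx(1.0)


def test_random_labels_ari_near_zero(two_region_fixture):
    m, labels = two_region_fixture
    rng = np.random.default_rng(33)
    emb = pca_embedding(m)
    aris = [
        clustering_metrics(m, rng.integers(0, 2, m.n_spots), labels, embedding=emb).ari
        for _ in range(100)
    ]
    assert abs(np.mean(aris)) < 0.05


def test_internal_indices_match_brute_force_on_toy_embedding():
    """Silhouette and Calinski-Harabasz recomputed from their definitions."""
    rng = np.random.default_rng(34)
    emb = np.vstack([rng.normal(0, 0.3, (15, 2)), rng.normal(3, 0.3, (15, 2))])
    labels = np.repeat([0, 1], 15)

    # hand-rolled silhouette
    def dist(a, b):
        return np.linalg.norm(a - b)

    sil_vals = []
    for i in range(30):
        same = [dist(emb[i], emb[j]) for j in range(30) if labels[j] == labels[i] and j != i]
        other = [dist(emb[i], emb[j]) for j in range(30) if labels[j] != labels[i]]
        a, b = np.mean(same), np.mean(other)
        sil_vals.append((b - a) / max(a, b))
    # hand-rolled Calinski-Harabasz
    overall = emb.mean(axis=0)
    bgss = sum(
        (labels == c).sum() * ((emb[labels == c].mean(axis=0) - overall) ** 2).sum()
        for c in (0, 1)
    )
    wgss = sum(
        ((emb[labels == c] - emb[labels == c].mean(axis=0)) ** 2).sum() for c in (0, 1)
    )
    ch = (bgss / 1) / (wgss / 28)

    # compare against the package's implementation on the same embedding
    m = sb.SpatialMatrix(np.abs(emb) + 1.0, rng.uniform(0, 1, (30, 2)))
    rep = clustering_metrics(m, labels, embedding=emb)
    assert rep.silhouette == pytest.approx(np.mean(sil_vals), rel=1e-9)
    assert rep.calinski_harabasz == pytest.approx(ch, rel=1e-9)


def test_single_cluster_internal_indices_undefined(two_region_fixture):
    m, _ = two_region_fixture
    rep = clustering_metrics(m, np.zeros(m.n_spots, dtype=int))
    assert rep.silhouette is None and rep.calinski_harabasz is None


def test_pca_embedding_requires_complete_matrix(tiny_matrix):
    with pytest.raises(ValueError):
        pca_embedding(tiny_matrix)
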