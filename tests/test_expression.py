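"""Probe-level t-tests and the gene-calling rule."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from l1host import (
    ExpressionExperiment, call_genes, probe_tests, select_alpha,
    SimulationConfig, simulate_expression,
)


def make_experiment(values, probe_map, n_test, n_control, design="unpaired", ip=False):
    samples = [f"T{i}" for i in range(n_test)] + [f"C{i}" for i in range(n_control)]
    matrix = pd.DataFrame(values, index=list(probe_map), columns=samples, dtype=float)
    groups = pd.Series(["test"] * n_test + ["control"] * n_control, index=samples)
    return ExpressionExperiment("exp", matrix, groups, probe_map, design=design, ip_derived=ip)


# --- alpha selection --------------------------------------------------------

@pytest.mark.parametrize("n_test,n_control,ip,expected", [
    (5, 5, False, 0.01),
    (2, 6, False, 0.05),
    (6, 2, False, 0.05),
    (8, 8, True, 0.05),
    (3, 3, False, 0.01),
])
def test_select_alpha_rules(n_test, n_control, ip, expected):
    assert select_alpha(n_test, n_control, ip) == expected


def test_select_alpha_rejects_singleton_groups():
    with pytest.raises(ValueError):
        select_alpha(1, 5, False)


# --- probe tests ------------------------------------------------------------

def test_constant_probe_is_uninformative():
    exp = make_experiment([[3.0] * 8], {"p1": ("g1",)}, 4, 4)
    p = probe_tests(exp)
    assert p.loc["p1", "p_up"] == 1.0 and p.loc["p1", "p_down"] == 1.0


def test_shifted_probe_matches_one_sided_t_oracle(rng):
    test_vals = rng.normal(10, 1, 5)
    ctrl_vals = rng.normal(7, 1, 5)
    exp = make_experiment([np.concatenate([test_vals, ctrl_vals])], {"p1": ("g1",)}, 5, 5)
    p = probe_tests(exp)
    mt, mc = test_vals.mean(), ctrl_vals.mean()
    sp2 = (np.sum((test_vals - mt) ** 2) + np.sum((ctrl_vals - mc) ** 2)) / 8
    t = (mt - mc) / math.sqrt(sp2 * (2 / 5))
    assert p.loc["p1", "p_up"] == pytest.approx(float(stats.t.sf(t, 8)))
    assert p.loc["p1", "p_down"] == pytest.approx(float(stats.t.cdf(t, 8)))
    assert p.loc["p1", "p_down"] > 0.999


def test_one_sided_pair_is_complementary(rng):
    values = rng.normal(8, 1, size=(50, 10))
    exp = make_experiment(values, {f"p{i}": (f"g{i}",) for i in range(50)}, 5, 5)
    p = probe_tests(exp)
    assert np.all(np.minimum(p["p_up"], p["p_down"]) <= 0.5 + 1e-12)
    assert np.allclose(p["p_up"] + p["p_down"], 1.0)


def test_paired_design_matches_scipy(rng):
    values = rng.normal(8, 1, size=(20, 8))
    exp = make_experiment(values, {f"p{i}": (f"g{i}",) for i in range(20)},
                          4, 4, design="paired")
    p = probe_tests(exp)
    T, C = values[:, :4], values[:, 4:]
    for i in range(20):
        t_ref, p_ref = stats.ttest_rel(T[i], C[i], alternative="greater")
        assert p.iloc[i]["p_up"] == pytest.approx(p_ref)


def test_missing_values_skip_probe_only_when_undertested():
    values = [[1.0, 2.0, np.nan, 5.0, 5.5, 6.0],
              [1.0, np.nan, np.nan, 5.0, 5.5, 6.0]]
    exp = make_experiment(values, {"ok": ("g1",), "skip": ("g2",)}, 3, 3)
    p = probe_tests(exp)
    assert not np.isnan(p.loc["ok", "p_up"])
    assert np.isnan(p.loc["skip", "p_up"])     # only one usable test sample


def test_two_sided_mode_assigns_p_to_observed_direction(rng):
    values = rng.normal(8, 1, size=(30, 10))
    exp = make_experiment(values, {f"p{i}": (f"g{i}",) for i in range(30)}, 5, 5)
    p1 = probe_tests(exp, mode="one_sided")
    p2 = probe_tests(exp, mode="two_sided")
    favored = np.where(p1["p_up"] < p1["p_down"], p2["p_up"], p2["p_down"])
    other = np.where(p1["p_up"] < p1["p_down"], p2["p_down"], p2["p_up"])
    assert np.allclose(favored, 2 * np.minimum(p1["p_up"], p1["p_down"]))
    assert np.all(other == 1.0)


# --- gene calling -----------------------------------------------------------

def _probe_p(mapping):
    return pd.DataFrame(mapping, index=["p_up", "p_down"]).T


def _dummy_experiment(probe_map, n=5):
    values = np.zeros((len(probe_map), 2 * n))
    return make_experiment(values, probe_map, n, n)


def test_single_unique_probe_calls_gene():
    exp = _dummy_experiment({"u1": ("g1",)})
    probe_p = _probe_p({"u1": [0.001, 0.999]})
    calls = call_genes(exp, alpha=0.01, probe_p=probe_p)
    assert calls.frame.loc["g1", "up"] and not calls.frame.loc["g1", "down"]


def test_homologous_only_gene_needs_two_significant_probes():
    exp = _dummy_experiment({"h1": ("g1", "g2"), "h2": ("g1", "g3")})
    one_sig = _probe_p({"h1": [0.001, 0.999], "h2": [0.5, 0.5]})
    calls = call_genes(exp, alpha=0.01, probe_p=one_sig)
    assert not calls.frame.loc["g1", "up"]
    both_sig = _probe_p({"h1": [0.001, 0.999], "h2": [0.005, 0.995]})
    calls = call_genes(exp, alpha=0.01, probe_p=both_sig)
    assert calls.frame.loc["g1", "up"]


def test_unique_probe_route_overrides_homologous_count():
    # the gene has a unique probe, so the homologous evidence is not the route
    exp = _dummy_experiment({"u1": ("g1",), "h1": ("g1", "g2"), "h2": ("g1", "g3")})
    probe_p = _probe_p({"u1": [0.9, 0.1], "h1": [0.001, 0.999], "h2": [0.001, 0.999]})
    calls = call_genes(exp, alpha=0.01, probe_p=probe_p)
    assert not calls.frame.loc["g1", "up"]


def test_conflicting_directions_resolved_by_best_p():
    exp = _dummy_experiment({"u1": ("g1",), "u2": ("g1",)})
    probe_p = _probe_p({"u1": [0.0001, 0.9999], "u2": [0.999, 0.002]})
    calls = call_genes(exp, alpha=0.01, probe_p=probe_p)
    row = calls.frame.loc["g1"]
    assert row["conflict"] and row["up"] and not row["down"]


def test_gene_without_testable_probe_excluded():
    exp = _dummy_experiment({"u1": ("g1",), "u2": ("g2",)})
    probe_p = _probe_p({"u1": [0.5, 0.5], "u2": [np.nan, np.nan]})
    calls = call_genes(exp, alpha=0.01, probe_p=probe_p)
    assert "g2" not in calls.frame.index


def brute_force_calls(experiment, alpha):
    """Independent probe-by-probe reimplementation of the calling rule."""
    T = experiment.matrix[experiment.test_samples]
    C = experiment.matrix[experiment.control_samples]
    per_gene = {}
    for probe, genes in experiment.probe_map.items():
        x, y = T.loc[probe].dropna(), C.loc[probe].dropna()
        if len(x) < 2 or len(y) < 2:
            continue
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            p_up = p_down = 1.0
            if x.mean() != y.mean():
                p_up, p_down = (0.0, 1.0) if x.mean() > y.mean() else (1.0, 0.0)
        else:
            _, p_up = stats.ttest_ind(x, y, equal_var=True, alternative="greater")
            _, p_down = stats.ttest_ind(x, y, equal_var=True, alternative="less")
        for g in genes:
            per_gene.setdefault(g, []).append((len(genes) == 1, p_up, p_down))
    result = {}
    for g, probes in per_gene.items():
        unique = [p for p in probes if p[0]]
        route = unique if unique else probes
        need = 1 if unique else 2
        n_up = sum(p[1] < alpha for p in route)
        n_down = sum(p[2] < alpha for p in route)
        up, down = n_up >= need, n_down >= need
        if up and down:
            best_up = min(p[1] for p in route)
            best_down = min(p[2] for p in route)
            up, down = best_up < best_down, best_down <= best_up
        result[g] = (up, down)
    return result


def test_calls_match_brute_force_oracle_on_synthetic_experiments():
    for seed in range(25):
        cfg = SimulationConfig(seed=seed, n_genes=60, n_samples_per_group=4,
                               de_effect_size=1.5)
        gene_ids = [f"g{i}" for i in range(60)]
        l1_set = set(gene_ids[:12])
        exp, _ = simulate_expression(cfg, gene_ids, l1_set)
        calls = call_genes(exp, alpha=0.05)
        expected = brute_force_calls(exp, alpha=0.05)
        got = {g: (bool(r["up"]), bool(r["down"])) for g, r in calls.frame.iterrows()}
        assert got == expected


def test_mutual_exclusivity_and_alpha_monotonicity():
    cfg = SimulationConfig(seed=3, n_genes=300)
    gene_ids = [f"g{i}" for i in range(300)]
    exp, _ = simulate_expression(cfg, gene_ids, set(gene_ids[:60]))
    loose = call_genes(exp, alpha=0.05)
    strict = call_genes(exp, alpha=0.005)
    assert not (loose.frame["up"] & loose.frame["down"]).any()
    # raising alpha never removes a call (conflict-free genes)
    clean = ~loose.frame["conflict"]
    for col in ("up", "down"):
        assert (strict.frame.loc[clean, col] <= loose.frame.loc[clean, col]).all()
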