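"""Multi-environment ANOVA, heritability, BLUEs, trait correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

import wheatgs as w
from wheatgs.phenotypes import VarianceComponents


def make_table(values: dict) -> pd.DataFrame:
    """Long table from {(line, env, rep): value}."""
    rows = [
        {"line": l, "environment": e, "replication": r, "trait": "T",
         "value": v}
        for (l, e, r), v in values.items()
    ]
    return pd.DataFrame(rows)


def brute_force_ss(df: pd.DataFrame):
    """Independent SS decomposition by explicit cell-mean sums."""
    y = df.set_index(["line", "environment", "replication"])["value"]
    lines = sorted({i[0] for i in y.index})
    envs = sorted({i[1] for i in y.index})
    reps = sorted({i[2] for i in y.index})
    g, e, r = len(lines), len(envs), len(reps)
    grand = y.mean()
    ss_g = sum(
        e * r * (np.mean([y[(i, j, k)] for j in envs for k in reps]) - grand) ** 2
        for i in lines
    )
    ss_e = sum(
        g * r * (np.mean([y[(i, j, k)] for i in lines for k in reps]) - grand) ** 2
        for j in envs
    )
    ss_r = sum(
        g * (np.mean([y[(i, j, k)] for i in lines])
             - np.mean([y[(i, j, kk)] for i in lines for kk in reps])) ** 2
        for j in envs for k in reps
    )
    ss_ge = 0.0
    for i, j in itertools.product(lines, envs):
        mg = np.mean([y[(i, jj, k)] for jj in envs for k in reps])
        me = np.mean([y[(ii, j, k)] for ii in lines for k in reps])
        mge = np.mean([y[(i, j, k)] for k in reps])
        ss_ge += r * (mge - mg - me + grand) ** 2
    ss_tot = ((y - grand) ** 2).sum()
    return ss_g, ss_e, ss_r, ss_ge, ss_tot - ss_g - ss_e - ss_r - ss_ge


class TestAnova:
    def test_2x2x2_mean_squares_match_brute_force(self):
        rng = np.random.default_rng(4)
        vals = {
            (l, e, r): float(rng.normal())
            for l in ("A", "B") for e in ("E1", "E2") for r in ("R1", "R2")
        }
        df = make_table(vals)
        vc = w.anova_components(df, "T")
        ss_g, ss_e, ss_r, ss_ge, ss_eps = brute_force_ss(df)
        assert vc.ms["MS_G"] == pytest.approx(ss_g / 1)
        assert vc.ms["MS_E"] == pytest.approx(ss_e / 1)
        assert vc.ms["MS_R"] == pytest.approx(ss_r / 2)
        assert vc.ms["MS_GE"] == pytest.approx(ss_ge / 1)
        assert vc.ms["MS_eps"] == pytest.approx(ss_eps / 2)

    def test_sum_of_squares_conservation(self, clean_panel):
        _, p, _, _ = clean_panel
        vc = w.anova_components(p, "T")
        ss_sum = sum(vc.ms[f"MS_{k}"] * vc.df[k]
                     for k in ("G", "E", "R", "GE", "eps"))
        y = p[p["trait"] == "T"]["value"].to_numpy()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert ss_sum == pytest.approx(ss_tot, rel=1e-8)

    def test_ratio_and_textbook_estimators_reported(self, clean_panel):
        _, p, _, _ = clean_panel
        vc = w.anova_components(p, "T")
        assert vc.sigma2_G == pytest.approx(vc.sigma2_G_ratio)
        vt = w.anova_components(p, "T", estimator="textbook")
        assert vt.sigma2_G == pytest.approx(vt.sigma2_G_textbook)
        # both variants agree on sigma_GE^2 and sigma_eps^2
        assert vc.sigma2_GE == pytest.approx(vt.sigma2_GE)
        assert vc.sigma2_eps == pytest.approx(vt.sigma2_eps)

    def test_equal_interaction_and_error_ms_give_zero_sigma_ge(self):
        # additive data: GE mean square equals error mean square in
        # expectation; construct exactly additive responses -> sigma_GE = 0
        vals = {}
        for li, l in enumerate(("A", "B", "C")):
            for ei, e in enumerate(("E1", "E2")):
                for r in ("R1", "R2"):
                    vals[(l, e, r)] = float(li + 10 * ei)
        vc = w.anova_components(make_table(vals), "T")
        assert vc.sigma2_GE == 0.0
        assert vc.ms["MS_GE"] == pytest.approx(vc.ms["MS_eps"], abs=1e-12)

    def test_negative_estimates_truncated_and_flagged(self):
        # pure noise with tiny genotype signal often yields negative moments
        rng = np.random.default_rng(11)
        vals = {
            (l, e, r): float(rng.normal())
            for l in ("A", "B", "C") for e in ("E1", "E2")
            for r in ("R1", "R2")
        }
        vc = w.anova_components(make_table(vals), "T")
        for name in vc.truncated:
            assert getattr(vc, name) == 0.0

    def test_unbalanced_layout_flagged(self):
        rng = np.random.default_rng(5)
        vals = {
            (l, e, r): float(rng.normal())
            for l in ("A", "B", "C") for e in ("E1", "E2")
            for r in ("R1", "R2")
        }
        df = make_table(vals).drop(index=0)
        vc = w.anova_components(df, "T")
        assert not vc.balanced

    def test_too_few_levels_rejected(self):
        vals = {("A", "E1", r): 1.0 for r in ("R1", "R2")}
        vals.update({("B", "E1", r): 2.0 for r in ("R1", "R2")})
        with pytest.raises(ValueError, match=">=2"):
            w.anova_components(make_table(vals), "T")


class TestHeritability:
    def _vc(self, s2g, s2ge, s2e, e=3, r=3):
        return VarianceComponents(
            trait="T", e=e, r=r, n_geno=10, ms={}, df={},
            sigma2_G=s2g, sigma2_GE=s2ge, sigma2_eps=s2e,
            sigma2_G_ratio=s2g, sigma2_G_textbook=s2g, estimator="ratio",
        )

    def test_direct_substitution(self):
        h2_plot, h2_mean = w.heritability(self._vc(1.0, 1.0, 1.0))
        assert h2_plot == pytest.approx(1 / 3)
        assert h2_mean == pytest.approx(1 / (1 + 1 / 3 + 1 / 9))

    def test_no_nongenetic_variance_gives_one(self):
        assert w.heritability(self._vc(2.0, 0.0, 0.0)) == (1.0, 1.0)

    def test_zero_genetic_variance_gives_zero(self):
        assert w.heritability(self._vc(0.0, 1.0, 1.0)) == (0.0, 0.0)

    def test_all_zero_components_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            w.heritability(self._vc(0.0, 0.0, 0.0))

    def test_mean_heritability_at_least_plot_level(self, clean_panel):
        _, p, _, _ = clean_panel
        vc = w.anova_components(p, "T")
        h2_plot, h2_mean = w.heritability(vc)
        assert h2_mean >= h2_plot

    def test_plot_heritability_recovered_at_trial_scale(self):
        """Textbook-estimator H2_plot is unbiased at the 166 x 3 x 3 scale
        (mean over simulations within +-0.05 of the generating value)."""
        target = 1.0 / 3.0
        est = []
        for seed in range(40):
            cfg = w.SimulationConfig(
                seed=seed, n_lines=166, n_markers=200, missing_rate_max=0.0,
                variance_targets={"T": (1.0, 1.0, 1.0, 1.0)},
            )
            _, p, _ = w.simulate_panel(cfg)
            vc = w.anova_components(p, "T", estimator="textbook")
            est.append(w.heritability(vc)[0])
        assert abs(np.mean(est) - target) < 0.05


class TestBlue:
    def test_balanced_equals_line_mean(self, clean_panel):
        _, p, _, _ = clean_panel
        blue = w.compute_blue(p, "T")
        means = p[p["trait"] == "T"].groupby("line")["value"].mean()
        assert np.allclose(blue.sort_index(), means.sort_index())

    def test_environment_shift_leaves_differences_unchanged(self, clean_panel):
        _, p, _, _ = clean_panel
        shifted = p.copy()
        mask = shifted["environment"] == "E1"
        shifted.loc[mask, "value"] += 100.0
        a = w.compute_blue(p, "T").sort_index()
        b = w.compute_blue(shifted, "T").sort_index()
        assert np.allclose(np.diff(a), np.diff(b))

    def test_translation_equivariance(self, clean_panel):
        _, p, _, _ = clean_panel
        shifted = p.copy()
        shifted["value"] += 3.5
        a = w.compute_blue(p, "T").sort_index()
        b = w.compute_blue(shifted, "T").sort_index()
        assert np.allclose(b, a + 3.5)

    def test_unbalanced_matches_normal_equations(self):
        # 3 lines x 2 environments, one cell absent
        rows = []
        vals = {("A", "E1"): 1.0, ("A", "E2"): 2.0, ("B", "E1"): 3.0,
                ("B", "E2"): 5.0, ("C", "E1"): 4.0}
        for (l, e), v in vals.items():
            rows.append({"line": l, "environment": e, "replication": "R1",
                         "trait": "T", "value": v})
        df = pd.DataFrame(rows)
        blue = w.compute_blue(df, "T")
        # explicit dense solve: mu+G per line with env sum-to-zero
        X = np.array([
            # A  B  C  e1 (e2 = -e1)
            [1, 0, 0, 1],
            [1, 0, 0, -1],
            [0, 1, 0, 1],
            [0, 1, 0, -1],
            [0, 0, 1, 1],
        ], dtype=float)
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(blue[["A", "B", "C"]], beta[:3])

    def test_disconnected_design_rejected(self):
        rows = [
            {"line": "A", "environment": "E1", "replication": "R1",
             "trait": "T", "value": 1.0},
            {"line": "B", "environment": "E2", "replication": "R1",
             "trait": "T", "value": 2.0},
        ]
        with pytest.raises(ValueError, match="disconnected"):
            w.compute_blue(pd.DataFrame(rows), "T")


class TestCorrelations:
    def test_self_and_negated_traits(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        blues = pd.DataFrame({"A": x, "B": x, "C": -x})
        out = w.trait_correlations(blues)
        r_ab = out[(out.trait_a == "A") & (out.trait_b == "B")]["r"].iloc[0]
        r_ac = out[(out.trait_a == "A") & (out.trait_b == "C")]["r"].iloc[0]
        assert r_ab == pytest.approx(1.0)
        assert r_ac == pytest.approx(-1.0)

    def test_five_point_hand_dataset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # hand Pearson: cov / (sd_x sd_y)
        r_hand = ((x - 3) * (y - 3)).sum() / np.sqrt(
            ((x - 3) ** 2).sum() * ((y - 3) ** 2).sum()
        )
        out = w.trait_correlations(pd.DataFrame({"X": x, "Y": y}))
        assert out["r"].iloc[0] == pytest.approx(r_hand, abs=1e-12)

    def test_constant_trait_flagged(self):
        blues = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]})
        out = w.trait_correlations(blues)
        assert out["stars"].iloc[0] == "undefined"

    def test_significance_stars(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 50)
        strong = x + rng.normal(scale=0.01, size=50)
        out = w.trait_correlations(pd.DataFrame({"A": x, "B": strong}))
        assert out["stars"].iloc[0] == "***"
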