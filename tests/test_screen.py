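import numpy as np
import pandas as pd
import pytest

from gscoex.screen import (
    CovariateTable,
    SelectionPolicy,
    collinearity_diagnostics,
    partition_variance_two_step,
    select_covariates,
)


def _cov_table(n, rng, extra=None):
    data = pd.DataFrame(
        {
            "Age": rng.normal(45, 15, n),
            "Sex": (rng.random(n) < 0.8).astype(float),
            "GS3_SCZ": rng.normal(size=n),
            "RIN": rng.normal(7.5, 1, n),
            "qSV_1": rng.normal(size=n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    if extra is not None:
        for k, v in extra.items():
            data[k] = v
    roles = {c: ("interest" if c.startswith("GS") else "non_interest") for c in data}
    return CovariateTable(data, roles)


def _expr(values, columns):
    return pd.DataFrame(
        np.atleast_2d(values),
        index=[f"g{i}" for i in range(np.atleast_2d(values).shape[0])],
        columns=columns,
    )


class TestPartitionVariance:
    def test_noiseless_single_effect_attributes_all_variance(self, rng):
        cov = _cov_table(500, rng)
        y = 2.0 * cov.data["Age"].to_numpy()
        vft = partition_variance_two_step(_expr(y, cov.data.index), cov)
        assert vft.fractions.loc["g0", "Age"] > 0.97
        assert vft.fractions.loc["g0", "Sex"] < 0.02
        assert vft.fractions.loc["g0", "residual"] < 0.02

    def test_pure_noise_gene_has_small_fractions(self, rng):
        cov = _cov_table(80, rng)
        y = rng.normal(size=80)
        vft = partition_variance_two_step(_expr(y, cov.data.index), cov)
        bio = vft.fractions[vft.biological_covariates]
        assert (bio.loc["g0"] < 0.15).all()

    def test_planted_score_fraction_recovered(self, rng):
        # 200 genes constructed so the score explains 10% of variance
        cov = _cov_table(80, rng)
        s = cov.data["GS3_SCZ"].to_numpy()
        s = (s - s.mean()) / s.std()
        Y = np.sqrt(0.1) * s + np.sqrt(0.9) * rng.normal(size=(200, 80))
        vft = partition_variance_two_step(_expr(Y, cov.data.index), cov)
        mean_frac = vft.fractions["GS3_SCZ"].mean()
        assert abs(mean_frac - 0.10) < 0.04

    def test_matches_incremental_r2_oracle(self, rng):
        cov = _cov_table(60, rng)
        Y = rng.normal(size=(8, 60))
        vft = partition_variance_two_step(_expr(Y, cov.data.index), cov)
        # brute-force oracle: explicit least squares, drop-one incremental R^2
        tech = vft.technical_covariates
        bio = vft.biological_covariates
        X1 = np.column_stack([np.ones(60)] + [cov.data[c] for c in tech])
        for g in range(8):
            y = Y[g]
            b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
            resid = y - X1 @ b1
            tss = ((y - y.mean()) ** 2).sum()
            tech_frac = 1 - (resid**2).sum() / tss

            def r2(cols):
                X = np.column_stack([np.ones(60)] + [cov.data[c] for c in cols])
                b, *_ = np.linalg.lstsq(X, resid, rcond=None)
                rr = resid - X @ b
                t = ((resid - resid.mean()) ** 2).sum()
                return 1 - (rr**2).sum() / t

            full = r2(bio)
            assert vft.fractions.iloc[g]["technical"] == pytest.approx(
                tech_frac, abs=1e-10
            )
            for c in bio:
                inc = full - r2([x for x in bio if x != c])
                assert vft.fractions.iloc[g][c] == pytest.approx(
                    max(inc, 0), abs=1e-10
                )

    def test_two_stage_composition_on_orthogonal_design(self, rng):
        # with orthogonal covariates the two-stage fractions recompose the
        # total explained variance of a joint fit
        n = 200
        M = rng.normal(size=(n, 5))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))
        data = pd.DataFrame(
            Q,
            columns=["Age", "Sex", "GS3_SCZ", "RIN", "qSV_1"],
            index=[f"s{i}" for i in range(n)],
        )
        roles = {c: ("interest" if c.startswith("GS") else "non_interest") for c in data}
        cov = CovariateTable(data, roles)
        y = Q @ np.array([1.0, 0.5, 2.0, -1.0, 0.7]) + 0.5 * rng.normal(size=n)
        vft = partition_variance_two_step(_expr(y, data.index), cov)
        f = vft.fractions.iloc[0]
        tech = f["technical"]
        stage2_total = sum(f[c] for c in vft.biological_covariates)
        combined = tech + stage2_total * (1 - tech)
        Xall = np.column_stack([np.ones(n), Q])
        b, *_ = np.linalg.lstsq(Xall, y, rcond=None)
        resid = y - Xall @ b
        joint_r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert combined == pytest.approx(joint_r2, abs=1e-6)

    def test_rank_deficient_design_names_columns(self, rng):
        cov = _cov_table(50, rng)
        data = cov.data.copy()
        data["qSV_2"] = data["qSV_1"]  # exact duplicate
        roles = dict(cov.roles)
        roles["qSV_2"] = "non_interest"
        cov2 = CovariateTable(data, roles)
        with pytest.raises(np.linalg.LinAlgError, match="qSV"):
            partition_variance_two_step(_expr(rng.normal(size=50), data.index), cov2)

    def test_too_few_samples_refused(self, rng):
        cov = _cov_table(5, rng)
        with pytest.raises(ValueError):
            partition_variance_two_step(_expr(rng.normal(size=5), cov.data.index), cov)


class TestCollinearity:
    def test_duplicated_column_flagged_infinite(self, rng):
        cov = _cov_table(100, rng)
        data = cov.data.copy()
        data["qSV_dup"] = data["qSV_1"]
        roles = dict(cov.roles)
        roles["qSV_dup"] = "non_interest"
        rep = collinearity_diagnostics(CovariateTable(data, roles))
        assert np.isinf(rep.vif["qSV_1"]) and np.isinf(rep.vif["qSV_dup"])
        assert "qSV_1" in rep.flagged and "qSV_dup" in rep.flagged

    def test_independent_covariates_have_unit_vif(self, rng):
        n = 5000
        data = pd.DataFrame(
            rng.normal(size=(n, 4)),
            columns=list("abcd"),
            index=[f"s{i}" for i in range(n)],
        )
        rep = collinearity_diagnostics(
            CovariateTable(data, {c: "non_interest" for c in data})
        )
        assert (rep.vif < 1.05).all()
        assert rep.flagged == []

    def test_near_collinear_pair_flagged_with_closed_form_vif(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = -x + np.sqrt(1 / 0.99**2 - 1) * rng.normal(size=n)  # r ~ -0.99
        data = pd.DataFrame(
            {"neurons": x, "oligodendrocytes": y, "Age": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        rep = collinearity_diagnostics(
            CovariateTable(data, {c: "non_interest" for c in data}), vif_threshold=10
        )
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        expected = 1 / (1 - r2)
        assert rep.vif["neurons"] == pytest.approx(expected, rel=0.05)
        assert "neurons" in rep.flagged and "oligodendrocytes" in rep.flagged

    def test_constant_column_flagged_not_crash(self, rng):
        data = pd.DataFrame(
            {"a": rng.normal(size=50), "b": np.ones(50)},
            index=[f"s{i}" for i in range(50)],
        )
        rep = collinearity_diagnostics(
            CovariateTable(data, {c: "non_interest" for c in data})
        )
        assert np.isinf(rep.vif["b"])
        assert "b" in rep.removable

    def test_correlation_matrix_contract(self, rng):
        cov = _cov_table(100, rng)
        rep = collinearity_diagnostics(cov)
        C = rep.correlation.to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        assert (rep.vif.dropna() >= 1 - 1e-9).all()


class TestSelection:
    def _vft(self, fractions):
        from gscoex.screen import VarianceFractionTable

        df = pd.DataFrame(fractions, index=["g0", "g1"])
        return VarianceFractionTable(df, ["RIN"], list(fractions))

    def test_strict_ordering_selects_higher_fraction(self, rng):
        vft = self._vft({"GS3": [0.012, 0.010], "GS5": [0.003, 0.001]})
        cov = _cov_table(100, rng)
        col = collinearity_diagnostics(cov)
        sel = select_covariates(
            vft, col, SelectionPolicy(candidates={"SCZ": ["GS3", "GS5"]}, n_per_trait=1)
        )
        assert sel.interest == ["GS3"]

    def test_tie_breaks_by_column_order(self, rng):
        vft = self._vft({"GS_a": [0.01, 0.01], "GS_b": [0.01, 0.01]})
        cov = _cov_table(100, rng)
        col = collinearity_diagnostics(cov)
        sel = select_covariates(
            vft,
            col,
            SelectionPolicy(candidates={"SCZ": ["GS_a", "GS_b"]}, n_per_trait=1),
        )
        assert sel.interest == ["GS_a"]

    def test_two_sets_per_trait_default(self, rng):
        vft = self._vft(
            {
                "GS3_SCZ": [0.011, 0.011],
                "GS5_SCZ": [0.007, 0.007],
                "GS1_SCZ": [0.001, 0.001],
            }
        )
        cov = _cov_table(100, rng)
        col = collinearity_diagnostics(cov)
        sel = select_covariates(
            vft,
            col,
            SelectionPolicy(candidates={"SCZ": ["GS3_SCZ", "GS5_SCZ", "GS1_SCZ"]}),
        )
        assert sel.interest == ["GS3_SCZ", "GS5_SCZ"]

    def test_empty_candidates_rejected(self, rng):
        vft = self._vft({"GS3": [0.01, 0.01]})
        cov = _cov_table(100, rng)
        col = collinearity_diagnostics(cov)
        with pytest.raises(ValueError):
            select_covariates(vft, col, SelectionPolicy(candidates={}))
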