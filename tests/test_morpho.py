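import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divaxes import morpho


def _table(mass, wing, tarsus, **cols):
    n = len(mass)
    base = {
        "individual_id": [f"i{k}" for k in range(n)],
        "site_id": cols.pop("site_id", ["s1"] * n),
        "group": cols.pop("group", ["g1"] * n),
        "sex": cols.pop("sex", ["male"] * n),
        "mass": mass,
        "wing": wing,
        "tarsus": tarsus,
    }
    base.update(cols)
    return pd.DataFrame(base)


# ----------------------------------------------------------- preprocess


def test_preprocess_log10_and_roundtrip():
    t = _table([10.0, 31.6], [80.0, 90.0], [25.0, 30.0])
    out = morpho.preprocess(t)
    assert out.loc[0, "mass"] == pytest.approx(1.0)
    assert np.allclose(10.0 ** out["wing"], out["wing_raw"], rtol=1e-12)


def test_preprocess_rejects_nonpositive_naming_record():
    t = _table([10.0, 0.0], [80.0, 90.0], [25.0, 30.0])
    with pytest.raises(ValueError, match="i1"):
        morpho.preprocess(t)


# ----------------------------------------------------------- size index


def test_size_index_hand_ols():
    # (x, y) = (0,0), (1,1), (2,0): residuals (-1/3, +2/3, -1/3)
    t = _table([10] * 3, [1.0, 10.0, 1.0], [1.0, 10.0, 100.0])
    logt = t.copy()
    logt[["mass", "wing", "tarsus"]] = np.log10(
        t[["mass", "wing", "tarsus"]]
    )
    res = morpho.size_index(logt)
    assert np.allclose(res, [-1 / 3, 2 / 3, -1 / 3])


def test_size_index_identities(rng):
    x = rng.uniform(1.3, 1.6, size=30)
    y = 1.1 * x + rng.normal(scale=0.02, size=30)
    t = _table([10] * 30, [1] * 30, [1] * 30)
    t["wing"], t["tarsus"] = y, x
    res = morpho.size_index(t)
    assert abs(res.sum()) < 1e-9
    assert abs(res @ x) < 1e-9  # orthogonal to the regressor


def test_size_index_perfect_line_zero_residuals():
    t = _table([10] * 3, [1] * 3, [1] * 3)
    t["tarsus"] = [1.0, 2.0, 3.0]
    t["wing"] = [2.0, 4.0, 6.0]
    assert np.allclose(morpho.size_index(t), 0.0, atol=1e-12)


def test_size_index_constant_tarsus_rejected():
    t = _table([10] * 4, [1.0, 2.0, 3.0, 4.0], [5.0] * 4)
    with pytest.raises(ValueError, match="tarsus"):
        morpho.size_index(t)


# -------------------------------------------------------------- anova


def test_factorial_anova_balanced_hand_computation():
    """Balanced 2x2 with cell means 0/2 (A) and 1/3 (B), ±0.5 replicates:
    SS_geo = 2, SS_sex = 8, SS_int = 0, MSE = 0.5 → F = 4, 16, 0."""
    rows = []
    means = {("A", "female"): 0.0, ("A", "male"): 2.0,
             ("B", "female"): 1.0, ("B", "male"): 3.0}
    i = 0
    for (geo, sex), mu in means.items():
        for d in (-0.5, 0.5):
            rows.append(
                {"individual_id": f"i{i}", "site_id": geo, "group": geo,
                 "sex": sex, "trait": mu + d}
            )
            i += 1
    df = pd.DataFrame(rows)
    tab = morpho.factorial_anova(df, "trait")
    assert tab.loc["geography", "F"] == pytest.approx(4.0)
    assert tab.loc["sex", "F"] == pytest.approx(16.0)
    assert tab.loc["geography:sex", "F"] == pytest.approx(0.0, abs=1e-10)


def test_factorial_anova_constant_trait_rejected():
    df = _table([10] * 8, [1] * 8, [1] * 8,
                site_id=["A"] * 4 + ["B"] * 4,
                sex=["male", "female"] * 4)
    with pytest.raises(ValueError, match="constant"):
        morpho.factorial_anova(df, "mass")


def test_factorial_anova_empty_cell_rejected():
    df = _table(list(range(1, 9)), [1] * 8, [1] * 8,
                site_id=["A"] * 4 + ["B"] * 4,
                sex=["male"] * 4 + ["male", "female", "female", "female"])
    with pytest.raises(ValueError, match="cell"):
        morpho.factorial_anova(df, "mass")


def test_subspecies_anova_with_and_without_sex(rng):
    df = _table(
        rng.normal(1.5, 0.05, 40), [1] * 40, [1] * 40,
        group=["g1"] * 20 + ["g2"] * 20,
        sex=["male", "female"] * 20,
    )
    df.loc[df.group == "g2", "mass"] += 0.3
    f_plain, p_plain = morpho.subspecies_anova(df, "mass")
    f_adj, p_adj = morpho.subspecies_anova(df, "mass", sex_covariate=True)
    assert p_plain < 1e-6 and p_adj < 1e-6
    assert f_plain > 0 and f_adj > 0


# ------------------------------------------------------- aicc / weights


def test_aicc_arithmetic():
    assert morpho.aicc(10, 3, 10.0) == pytest.approx(10.0)  # 6 + 24/6
    # correction term alone, n=12 k=3: 2*3*4/8 = 3
    assert morpho.aicc(12, 3, 12.0) - (12 * np.log(1.0) + 6) == pytest.approx(3.0)


def test_aicc_errors():
    with pytest.raises(ValueError):
        morpho.aicc(4, 3, 1.0)
    with pytest.raises(ValueError):
        morpho.aicc(10, 3, 0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    rss=st.floats(0.1, 1e6),
    bump=st.floats(0.01, 10.0),
    n=st.integers(8, 200),
    k=st.integers(2, 5),
)
def test_aicc_monotone_in_rss(rss, bump, n, k):
    assert morpho.aicc(n, k, rss + bump) > morpho.aicc(n, k, rss)


def test_akaike_weights_arithmetic():
    assert np.allclose(morpho.akaike_weights([0.0, 0.0]), [0.5, 0.5])
    w = morpho.akaike_weights([0.0, 2.0])
    assert np.round(w, 3).tolist() == [0.731, 0.269]
    w = morpho.akaike_weights([0.0, 14.0])
    assert w[0] > 0.999
    with pytest.raises(ValueError):
        morpho.akaike_weights([])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 100), min_size=1, max_size=8))
def test_akaike_weights_sum_to_one(deltas):
    deltas = [d - min(deltas) for d in deltas]
    assert morpho.akaike_weights(deltas).sum() == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------ model selection


def test_quadratic_truth_takes_all_weight(rng):
    x2 = np.linspace(-2, 2, 60)
    x1 = rng.standard_normal(60)
    y = 1.0 - 0.4 * x2**2 + rng.normal(scale=1e-6, size=60)
    comp = morpho.fit_climate_models(y, x1, x2)
    row = comp.set_index("model").loc["PC2+PC2^2"]
    assert row["weight"] == pytest.approx(1.0, abs=1e-6)
    assert row["delta_aicc"] == 0.0
    assert row["k"] == 4


def test_quadratic_never_increases_r_squared(rng):
    y = rng.standard_normal(40)
    x1, x2 = rng.standard_normal(40), rng.standard_normal(40)
    comp = morpho.fit_climate_models(y, x1, x2).set_index("model")
    assert comp.loc["PC1+PC1^2", "r_squared"] >= comp.loc["PC1", "r_squared"]
    assert comp.loc["PC2+PC2^2", "r_squared"] >= comp.loc["PC2", "r_squared"]


def test_aicc_penalty_can_prefer_linear(rng):
    """On pure-linear truth with few points, the quadratic's extra
    parameter should cost it the AICc ranking."""
    x = np.linspace(-1, 1, 12)
    y = 2 * x + rng.normal(scale=0.1, size=12)
    comp = morpho.fit_climate_models(y, x, rng.standard_normal(12))
    comp = comp.set_index("model")
    assert comp.loc["PC1", "aicc"] < comp.loc["PC1+PC1^2", "aicc"]


def test_model_comparison_invariants(rng):
    y = rng.standard_normal(30)
    comp = morpho.fit_climate_models(
        y, rng.standard_normal(30), rng.standard_normal(30)
    )
    assert (comp["delta_aicc"] == 0).sum() == 1
    assert comp["weight"].sum() == pytest.approx(1.0, abs=1e-9)
    assert comp["k"].tolist() == [3, 4, 3, 4]


def test_fit_climate_models_needs_enough_points():
    with pytest.raises(ValueError):
        morpho.fit_climate_models([1, 2, 3], [1, 2, 3], [1, 2, 3])
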