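"""Composite-score aggregation: standardization, rescale, label, bands."""

import numpy as np
import pandas as pd
import pytest

from pars.components import PARS_COMPONENTS
from pars.scoring import (
    ParsScoreModel,
    ScoringError,
    band,
    fit_label_threshold,
    fit_rescale,
    fit_standardization,
    label_high_risk,
    pars_composite,
    rescale,
)


def toy_table():
    return pd.DataFrame(
        {
            "ddi_score": [0, 3, 6, 9],
            "has_polypharmacy": [0, 0, 1, 1],
            "azcert_max": [0, 1, 2, 3],
            "acb_score": [1, 2, 3, 4],
            "sero_any": [0, 1, 1, 1],
        },
        index=list("ABCD"),
    )


def test_standardization_two_point_sample_sd():
    tab = pd.DataFrame({c: [0, 2] for c in PARS_COMPONENTS})
    p = fit_standardization(tab)
    assert np.allclose(p.mean, 1.0)
    assert np.allclose(p.sd, np.sqrt(2.0))
    assert not p.degenerate.any()


def test_constant_component_flagged_degenerate():
    tab = toy_table()
    tab["sero_any"] = 1
    with pytest.warns(UserWarning, match="constant component"):
        p = fit_standardization(tab)
    assert bool(p.degenerate["sero_any"])
    # degenerate component contributes z = 0
    z, _ = pars_composite(tab, p)
    assert (z["z_sero_any"] == 0).all()


def test_standardization_matches_numpy_oracle(small_components):
    p = fit_standardization(small_components)
    for c in PARS_COMPONENTS:
        vals = small_components[c].to_numpy(float)
        assert abs(p.mean[c] - vals.mean()) < 1e-12
        assert abs(p.sd[c] - vals.std(ddof=1)) < 1e-12


def test_composite_centering_at_reference_means():
    tab = toy_table()
    p = fit_standardization(tab)
    at_means = pd.DataFrame([p.mean], index=["m"])
    _, pars = pars_composite(at_means, p)
    assert abs(pars.iloc[0]) < 1e-12


def test_composite_matches_manual_recomputation():
    # frozen spreadsheet-style values for the 4-visit toy table
    expected = {"A": -1.1703420831, "B": -0.3055840815,
                "C": 0.5055840815, "D": 0.9703420831}
    tab = toy_table()
    _, pars = pars_composite(tab, fit_standardization(tab))
    for k, v in expected.items():
        assert abs(pars[k] - v) < 1e-9
    assert abs(pars.mean()) < 1e-12


def test_reference_mean_is_zero(small_components):
    res = ParsScoreModel(small_components).fit()
    assert abs(res.pars.mean()) < 1e-9


def test_rescale_params_and_anchors():
    p = fit_rescale([-1.0, 0.0, 3.0])
    assert (p.pars_min, p.pars_max) == (-1.0, 3.0)
    assert rescale(-1.0, p) == 0.0
    assert rescale(3.0, p) == 10.0
    assert rescale(1.0, p) == 5.0
    # out-of-reference values clip for display, extrapolate raw
    assert rescale(5.0, p) == 10.0
    assert rescale(5.0, p, clip=False) == 15.0


def test_degenerate_rescale_errors():
    p = fit_rescale([2.0])
    assert p.is_degenerate
    with pytest.raises(ScoringError):
        rescale(2.0, p)


def test_rescale_minmax_oracle():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=200)
    p = fit_rescale(vals)
    assert p.pars_min == vals.min() and p.pars_max == vals.max()
    out = rescale(vals, p)
    assert out.min() == 0.0 and out.max() == 10.0
    # rank preservation (monotone transform)
    assert (np.argsort(out) == np.argsort(vals)).all()


def test_label_threshold_linear_interpolation():
    assert fit_label_threshold([1, 2, 3, 4]).tau75 == 3.25
    assert fit_label_threshold([5, 5, 5]).tau75 == 5.0
    rng = np.random.default_rng(4)
    vals = rng.normal(size=1001)
    # sort-based oracle: linear interpolation between order statistics
    srt = np.sort(vals)
    pos = 0.75 * (len(vals) - 1)
    lo = int(np.floor(pos))
    exp = srt[lo] + (pos - lo) * (srt[lo + 1] - srt[lo])
    assert abs(fit_label_threshold(vals).tau75 - exp) < 1e-12


def test_label_inclusive_at_threshold():
    p = fit_label_threshold([1, 2, 3, 4])
    assert label_high_risk(p.tau75, p) == 1
    assert label_high_risk(p.tau75 - 1e-9, p) == 0


def test_label_prevalence_near_quarter_on_tie_free_sample():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=2000)
    p = fit_label_threshold(vals)
    prev = label_high_risk(vals, p).mean()
    assert abs(prev - 0.25) <= 1.0 / len(vals)


@pytest.mark.parametrize("x,expected", [
    (0.0, "low"), (2.99, "low"), (3.0, "moderate"), (5.99, "moderate"),
    (6.0, "high"), (10.0, "high"),
])
def test_band_boundaries(x, expected):
    assert band(x) == expected


@pytest.mark.parametrize("x", [-0.1, 10.1])
def test_band_rejects_out_of_range(x):
    with pytest.raises(ScoringError):
        band(x)


def test_train_reference_never_consults_held_out(small_components):
    ids = list(small_components.index)
    train = ids[: len(ids) // 2]
    res_full = ParsScoreModel(small_components).fit(reference=train)
    # delete the held-out rows entirely and refit: identical parameters
    res_train_only = ParsScoreModel(small_components.loc[train]).fit(reference=train)
    a, b = res_full.params, res_train_only.params
    assert a.standardization.mean.equals(b.standardization.mean)
    assert a.standardization.sd.equals(b.standardization.sd)
    assert a.rescale.pars_min == b.rescale.pars_min
    assert a.rescale.pars_max == b.rescale.pars_max
    assert a.label.tau75 == b.label.tau75


def test_results_frame_consistency(small_components):
    res = ParsScoreModel(small_components).fit()
    f = res.frame
    # composite equals mean of the five z columns
    zcols = [c for c in f.columns if c.startswith("z_")]
    assert np.allclose(f[zcols].mean(axis=1), f["pars"])
    # band consistent with the rescaled score
    assert all(band(x) == b for x, b in zip(f["pars_rescaled"], f["band"]))
    # rescale anchors on the reference set
    ref = res.reference_frame()
    assert ref["pars_rescaled"].min() == 0.0
    assert ref["pars_rescaled"].max() == 10.0
    # label from the stored threshold, inclusive
    assert (f["high_risk"] == (f["pars"] >= res.params.label.tau75).astype(int)).all()


def test_empty_reference_errors():
    with pytest.raises(ScoringError):
        fit_standardization(pd.DataFrame(columns=list(PARS_COMPONENTS)))
    with pytest.raises(ScoringError):
        fit_rescale([])
    with pytest.raises(ScoringError):
        fit_label_threshold([])
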