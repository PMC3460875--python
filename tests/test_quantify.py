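import numpy as np
import pandas as pd
import pytest

from refstab.io_tables import CtDataset
from refstab.published import validation_frames
from refstab.quantify import fold_change, reference_consistency


def _design(reps=3):
    rows = []
    for tissue in ("root",):
        for trt, tp in (("control", 0.0), ("dehydration", 2.0), ("dehydration", 10.0)):
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}_{trt}_{tp:g}_r{r}",
                        "tissue": tissue,
                        "treatment": trt,
                        "timepoint_h": tp,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _dataset(ct_by_gene, reps=3):
    samples = _design(reps)
    ct = pd.DataFrame(ct_by_gene, dtype=float)
    ct.index = samples.index
    return CtDataset(ct=ct.T, samples=samples)


def test_closed_form_fold_change():
    # noiseless: target drops 3 cycles, reference drops 1 -> 2^3 / 2^1 = 4
    ds = _dataset(
        {"tgt": [25] * 3 + [22] * 3 + [22] * 3, "ref": [20] * 3 + [19] * 3 + [19] * 3}
    )
    tab = fold_change(ds, ds, {"tgt": 2.0, "ref": 2.0}, "control 0 h", ["ref"])
    cell = tab.cell("tgt", "root", "dehydration 2 h")
    assert cell.fold_change == pytest.approx(4.0, abs=1e-12)
    assert cell.se_log2 == pytest.approx(0.0, abs=1e-12)


def test_pfaffl_efficiency_correction():
    ds = _dataset(
        {"tgt": [25] * 3 + [22] * 3 + [22] * 3, "ref": [20] * 3 + [19] * 3 + [19] * 3}
    )
    tab = fold_change(ds, ds, {"tgt": 1.9, "ref": 2.0}, "control 0 h", ["ref"])
    assert tab.cell("tgt", "root", "dehydration 2 h").fold_change == pytest.approx(
        1.9**3 / 2.0, abs=1e-9
    )


def test_calibrator_rows_exactly_one():
    rng = np.random.default_rng(2)
    ct = {
        "tgt": 25 + rng.normal(0, 0.3, 9),
        "ref": 20 + rng.normal(0, 0.2, 9),
    }
    ds = _dataset(ct)
    tab = fold_change(ds, ds, {"tgt": 2.0, "ref": 2.0}, "control 0 h", ["ref"])
    cal = tab.table[tab.table["condition"] == "control 0 h"]
    assert (cal["fold_change"] == 1.0).all()
    # replicate scatter still reported for genes other than the reference
    assert (cal.loc[cal["target"] == "tgt", "se_log2"] > 0).all()


def test_two_reference_scheme_is_geometric_mean_of_singles():
    rng = np.random.default_rng(4)
    ct = {
        "tgt": 25 + rng.normal(0, 0.5, 9),
        "r1": 20 + rng.normal(0, 0.2, 9),
        "r2": 22 + rng.normal(0, 0.2, 9),
    }
    ds = _dataset(ct)
    eff = {"tgt": 1.9, "r1": 1.87, "r2": 2.0}
    both = fold_change(ds, ds, eff, "control 0 h", ["r1", "r2"])
    one = fold_change(ds, ds, eff, "control 0 h", ["r1"])
    two = fold_change(ds, ds, eff, "control 0 h", ["r2"])
    for cond in ("dehydration 2 h", "dehydration 10 h"):
        fc_both = both.cell("tgt", "root", cond).fold_change
        fc_geo = np.sqrt(
            one.cell("tgt", "root", cond).fold_change
            * two.cell("tgt", "root", cond).fold_change
        )
        assert fc_both == pytest.approx(fc_geo, abs=1e-9)


def test_stable_reference_reduces_to_ddct():
    # reference constant across all samples, all E = 2 -> classic 2^-ddCT
    ds = _dataset(
        {"tgt": [25] * 3 + [23.5] * 3 + [21] * 3, "ref": [20.0] * 9}
    )
    tab = fold_change(ds, ds, {"tgt": 2.0, "ref": 2.0}, "control 0 h", ["ref"])
    # ddCT = (CT_t,cond - CT_ref,cond) - (CT_t,cal - CT_ref,cal)
    assert tab.cell("tgt", "root", "dehydration 2 h").fold_change == pytest.approx(
        2.0 ** -((23.5 - 20) - (25 - 20)), abs=1e-12
    )
    assert tab.cell("tgt", "root", "dehydration 10 h").fold_change == pytest.approx(
        2.0**4, abs=1e-12
    )


def test_normalizing_target_by_itself_is_unity():
    rng = np.random.default_rng(6)
    ds = _dataset({"tgt": 24 + rng.normal(0, 1.0, 9)})
    tab = fold_change(ds, ds, {"tgt": 1.9}, "control 0 h", ["tgt"])
    assert np.allclose(tab.table["fold_change"], 1.0, atol=1e-9)


def test_errors_on_missing_scheme_gene_and_calibrator():
    ds = _dataset({"tgt": [25] * 9})
    with pytest.raises(ValueError, match="absent"):
        fold_change(ds, ds, {}, "control 0 h", ["nope"])
    with pytest.raises(ValueError, match="calibrator"):
        fold_change(ds, ds, {}, "control 99 h", ["tgt"])


def test_consistency_flagger_on_published_validation_values():
    flagged = reference_consistency(validation_frames(), detection_threshold=2.0)
    cells = set(zip(flagged["target"], flagged["tissue"]))
    assert ("GmNAC19", "root") in cells and ("GmNAC19", "shoot") in cells
    assert ("GmNAC43", "root") in cells and ("GmNAC92", "root") in cells
    assert not any(t == "GmNAC85" for t, _ in cells)
    assert ("GmNAC43", "shoot") not in cells and ("GmNAC92", "shoot") not in cells


def test_consistency_flagger_degenerate_cases():
    agree = pd.DataFrame(
        {
            "target": ["t"] * 2,
            "tissue": ["root"] * 2,
            "condition": ["c1", "c1"],
            "scheme": ["a", "b"],
            "fold_change": [4.0, 4.0],
        }
    )
    frames = [agree[agree.scheme == s] for s in ("a", "b")]
    assert reference_consistency(frames, 2.0).empty
    assert reference_consistency(frames, 1.0).empty  # all above threshold 1
    with pytest.raises(ValueError):
        reference_consistency(frames[:1], 2.0)
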