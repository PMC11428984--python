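"""Panel data model: relative water content, I/O round trips, trait flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from apsi import (
    AssayPanel,
    PanelValidationError,
    SyntheticPanelConfig,
    classify_strain_traits,
    compute_rwc,
    generate_panel,
    load_panel,
    write_panel,
)
from apsi.synthetic import SYNTH_CONTROLS


class TestComputeRwc:
    @pytest.mark.parametrize(
        "fw,dw,tw,expected",
        [
            (3.0, 1.0, 3.0, 1.0),   # full turgor
            (1.0, 1.0, 3.0, 0.0),   # fully dry
            (2.0, 1.0, 3.0, 0.5),
        ],
    )
    def test_formula(self, fw, dw, tw, expected):
        assert compute_rwc(fw, dw, tw) == pytest.approx(expected)

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_rwc(1.0, 2.0, 2.0)

    def test_out_of_range_fresh_weight(self):
        with pytest.raises(ValueError, match="outside"):
            compute_rwc(3.5, 1.0, 3.0)

    def test_clip_mode_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert compute_rwc(3.5, 1.0, 3.0, clip=True) == pytest.approx(1.0)

    @given(
        dw=st.floats(0.1, 10),
        span=st.floats(0.5, 10),
        f1=st.floats(0.01, 0.99),
        f2=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_increasing_in_fresh_weight(self, dw, span, f1, f2):
        tw = dw + span
        lo, hi = sorted((f1, f2))
        r_lo = compute_rwc(dw + lo * span, dw, tw)
        r_hi = compute_rwc(dw + hi * span, dw, tw)
        assert 0.0 <= r_lo <= 1.0 and 0.0 <= r_hi <= 1.0
        assert r_hi >= r_lo
        if hi - lo > 1e-9:  # strict once above float rounding scale
            assert r_hi > r_lo


class TestPanelIO:
    def test_round_trip(self, tmp_path, small_noisy_panel):
        path = tmp_path / "panel.csv"
        write_panel(small_noisy_panel, path)
        back = load_panel(path, controls=small_noisy_panel.controls)
        assert back.strains == small_noisy_panel.strains
        for attr in ("plants", "fungal", "halos", "hormones", "binary"):
            a = getattr(small_noisy_panel, attr)
            b = getattr(back, attr)
            key = [c for c in a.columns if a[c].dtype == object or "id" in c or c in
                   ("condition", "fungus", "mode", "hormone", "assay", "outcome",
                    "day", "replicate", "time_h")]
            a = a.sort_values(list(a.columns)).reset_index(drop=True)
            b = b[a.columns].sort_values(list(a.columns)).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_empty_measurements_valid(self, tmp_path):
        path = tmp_path / "panel.csv"
        pd.DataFrame(columns=[
            "strain", "assay", "condition", "fungus", "mode", "hormone",
            "day", "time_h", "replicate", "value", "unit",
        ]).to_csv(path, index=False)
        panel = load_panel(path, strains={"A", "B"})
        assert panel.strains == {"A", "B"}
        assert len(panel.plants) == 0

    def test_reference_halo_row(self, tmp_path):
        """The reference phosphate halo for DSM7 (3.3 cm) loads as measured."""
        path = tmp_path / "panel.csv"
        path.write_text(
            "strain,assay,condition,fungus,mode,hormone,day,time_h,replicate,value,unit\n"
            "DSM7,phosphate_halo,,,,,,,1,3.3,cm\n"
        )
        panel = load_panel(path)
        assert panel.halos.loc[0, "halo_diameter"] == pytest.approx(3.3)
        assert panel.halos.loc[0, "assay"] == "phosphate"

    def test_invalid_condition_names_row(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "strain,assay,condition,fungus,mode,hormone,day,time_h,replicate,value,unit\n"
            "S1,fresh_weight,flooded,,,,31,,1,2.0,g\n"
        )
        with pytest.raises(PanelValidationError, match="row 2.*flooded"):
            load_panel(path)

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "strain,assay,condition,fungus,mode,hormone,day,time_h,replicate,value,unit\n"
            "S1,dry_weight,irrigated,,,,31,,1,2.0,g\n"
            "S1,dry_weight,irrigated,,,,31,,1,2.1,g\n"
        )
        with pytest.raises(PanelValidationError, match="duplicate"):
            load_panel(path)

    def test_negative_measurement_rejected(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "strain,assay,condition,fungus,mode,hormone,day,time_h,replicate,value,unit\n"
            "S1,root_length,irrigated,,,,31,,1,-3.0,cm\n"
        )
        with pytest.raises(PanelValidationError, match="negative"):
            load_panel(path)

    def test_wrong_unit_rejected(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "strain,assay,condition,fungus,mode,hormone,day,time_h,replicate,value,unit\n"
            "S1,root_length,irrigated,,,,31,,1,3.0,inch\n"
        )
        with pytest.raises(PanelValidationError, match="unit"):
            load_panel(path)


def _plant_rows(strain, condition, dw, rwc, root, stem, n, rng, sd=0.0):
    rows = []
    for rep in range(n):
        d = dw + (rng.normal(0, sd) if sd else 0.0)
        tw = d * 4
        r = np.clip(rwc + (rng.normal(0, sd / 10) if sd else 0.0), 0.01, 0.99)
        rows.append({
            "strain_id": strain, "condition": condition, "day": 31, "replicate": rep + 1,
            "dry_weight": d, "turgid_weight": tw, "fresh_weight": d + r * (tw - d),
            "root_length": root + (rng.normal(0, sd) if sd else 0.0),
            "stem_length": stem + (rng.normal(0, sd) if sd else 0.0),
        })
    return rows


class TestTraitClassification:
    def test_identical_to_control_all_false(self):
        rng = np.random.default_rng(0)
        rows = []
        for sid in ("CTRL", "S1", "S2"):
            rows += _plant_rows(sid, "irrigated", 1.0, 0.9, 8, 10, 5, rng, sd=0.05)
            rows += _plant_rows(sid, "drought", 0.5, 0.4, 6, 8, 5, rng, sd=0.05)
        panel = AssayPanel(
            strains={"S1", "S2"}, controls={"plant_negative": "CTRL"},
            plants=pd.DataFrame(rows),
        )
        flags = classify_strain_traits(panel)
        assert not flags["is_pgpr"].any()
        assert not flags["is_drought_protectant"].any()

    def test_growth_boost_flags_pgpr_only(self):
        """+50% root and stem under irrigation, control-level drought values."""
        rng = np.random.default_rng(1)
        rows = _plant_rows("CTRL", "irrigated", 1.0, 0.9, 8, 10, 6, rng, sd=0.2)
        rows += _plant_rows("CTRL", "drought", 0.5, 0.4, 6, 8, 6, rng, sd=0.02)
        rows += _plant_rows("S1", "irrigated", 1.0, 0.9, 12, 15, 6, rng, sd=0.2)
        rows += _plant_rows("S1", "drought", 0.5, 0.4, 6, 8, 6, rng, sd=0.02)
        panel = AssayPanel(
            strains={"S1"}, controls={"plant_negative": "CTRL"},
            plants=pd.DataFrame(rows),
        )
        flags = classify_strain_traits(panel)
        assert bool(flags.loc["S1", "is_pgpr"])
        assert not bool(flags.loc["S1", "is_drought_protectant"])
        # oracle: direct group-mean comparison of combined length
        ctrl = [r for r in rows if r["strain_id"] == "CTRL" and r["condition"] == "irrigated"]
        s1 = [r for r in rows if r["strain_id"] == "S1" and r["condition"] == "irrigated"]
        mean = lambda rs: np.mean([r["root_length"] + r["stem_length"] for r in rs])
        assert mean(s1) > mean(ctrl)

    def test_drought_shift_flags_protectant(self):
        """Drought RWC and dry weight 3 pooled SD above control; oracle = Welch."""
        rng = np.random.default_rng(2)
        sd = 0.05
        rows = _plant_rows("CTRL", "drought", 0.5, 0.40, 6, 8, 8, rng, sd=sd)
        rows += _plant_rows("S1", "drought", 0.5 + 3 * sd, 0.40 + 3 * sd / 10, 6, 8, 8, rng, sd=sd)
        rows += _plant_rows("CTRL", "irrigated", 1.0, 0.9, 8, 10, 8, rng, sd=sd)
        rows += _plant_rows("S1", "irrigated", 1.0, 0.9, 8, 10, 8, rng, sd=sd)
        panel = AssayPanel(
            strains={"S1"}, controls={"plant_negative": "CTRL"},
            plants=pd.DataFrame(rows),
        )
        flags = classify_strain_traits(panel)
        assert bool(flags.loc["S1", "is_drought_protectant"])
        # Welch oracle on the generated replicates
        dro = pd.DataFrame(rows)
        dro = dro[dro["condition"] == "drought"]
        a = dro[dro["strain_id"] == "S1"]["dry_weight"]
        b = dro[dro["strain_id"] == "CTRL"]["dry_weight"]
        assert stats.ttest_ind(a, b, equal_var=False).pvalue < 0.05

    def test_missing_control_errors(self):
        rng = np.random.default_rng(3)
        panel = AssayPanel(
            strains={"S1"}, controls={},
            plants=pd.DataFrame(_plant_rows("S1", "irrigated", 1, 0.9, 8, 10, 3, rng)),
        )
        with pytest.raises(PanelValidationError, match="control"):
            classify_strain_traits(panel)


def test_generated_panels_pass_validation_round_trip(tmp_path, a6_profile):
    cfg = SyntheticPanelConfig(strains={"A6": a6_profile}, replicates=3,
                               noise_cv=0.1, seed=4)
    panel = generate_panel(cfg)
    panel.validate()
    assert set(SYNTH_CONTROLS.values()) <= panel.known_ids()
    path = tmp_path / "p.csv"
    write_panel(panel, path)
    load_panel(path, controls=panel.controls).validate()
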