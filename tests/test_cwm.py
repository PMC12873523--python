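"""CWM engine: dominance selection, bootstrap estimates, reference means,
fixed CWM and the ITV identity."""
import numpy as np
import pandas as pd
import pytest

import traitpart as tp


class TestSelectDominant:
    @pytest.mark.parametrize(
        "covers,expected",
        [
            # cumulative 0.50, 0.80, 0.95: 0.80 is not > 0.80, so C is needed
            ({"A": 50, "B": 30, "C": 15, "D": 5}, ["A", "B", "C"]),
            ({"X": 3.7}, ["X"]),
            # tie at 40 broken by identifier; 0.80 again not strictly exceeded
            ({"A": 40, "B": 40, "C": 20}, ["A", "B", "C"]),
        ],
    )
    def test_examples(self, covers, expected):
        assert tp.select_dominant_species(covers, 0.8) == expected

    def test_all_zero_covers_signal_empty_community(self):
        with pytest.raises(ValueError):
            tp.select_dominant_species({"A": 0.0, "B": 0.0})

    def test_cumulative_sum_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 12)
            cov = dict(zip([f"s{i}" for i in range(k)], rng.random(k) + 0.01))
            got = tp.select_dominant_species(cov, 0.8)
            # oracle: walk the sorted list, accumulate relative cover
            items = sorted(cov.items(), key=lambda sc: (-sc[1], sc[0]))
            tot = sum(cov.values())
            cum, want = 0.0, []
            for sp, c in items:
                want.append(sp)
                cum += c / tot
                if cum > 0.8:
                    break
            assert got == want


def _constant_traits(values: dict[str, float], n_rep: int = 5) -> pd.DataFrame:
    rows = []
    for sp, v in values.items():
        for r in range(1, n_rep + 1):
            rows.append(("p1", sp, r, "SLA", v))
    return pd.DataFrame(
        rows, columns=["plot_id", "species", "replicate", "trait", "value"]
    )


class TestBootstrapCwm:
    def test_degenerate_single_species_exact(self):
        covers = pd.DataFrame({"plot_id": "p1", "species": ["A"], "cover": [40.0]})
        traits = _constant_traits({"A": 5.0})
        for seed in (0, 1, 99):
            out = tp.bootstrap_cwm(traits, covers, seed=seed)
            assert out["value"].iloc[0] == pytest.approx(5.0, abs=0)
            assert out["bootstrap_se"].iloc[0] == 0.0

    def test_two_species_weighted_mean(self):
        covers = pd.DataFrame(
            {"plot_id": "p1", "species": ["A", "B"], "cover": [75.0, 25.0]}
        )
        traits = _constant_traits({"A": 10.0, "B": 2.0})
        for seed in (1, 2, 3):
            out = tp.bootstrap_cwm(traits, covers, 100, 200, seed)
            assert out["value"].iloc[0] == pytest.approx(8.0, abs=0.1)

    def test_error_shrinks_with_budget(self):
        covers = pd.DataFrame(
            {"plot_id": "p1", "species": ["A", "B"], "cover": [75.0, 25.0]}
        )
        traits = _constant_traits({"A": 10.0, "B": 2.0})

        def mean_err(n_res, n_draw):
            errs = [
                abs(
                    tp.bootstrap_cwm(traits, covers, n_res, n_draw, s)["value"].iloc[0]
                    - 8.0
                )
                for s in range(12)
            ]
            return np.mean(errs)

        assert mean_err(100, 200) < mean_err(5, 10)

    def test_missing_trait_coverage_yields_nan_not_exception(self):
        covers = pd.DataFrame(
            {"plot_id": ["p1", "p2"], "species": ["A", "B"], "cover": [50.0, 50.0]}
        )
        traits = _constant_traits({"A": 5.0})  # plot p2 has no trait data
        out = tp.bootstrap_cwm(traits, covers, seed=0)
        by_plot = out.set_index("plot_id")["value"]
        assert by_plot["p1"] == pytest.approx(5.0)
        assert np.isnan(by_plot["p2"])


class TestReferenceMeans:
    def _design(self):
        return tp.generate_design(1, 4, seed=0)

    def test_control_mean(self):
        design = self._design()
        ctrl = design[(design["nutrient"] == 0) & (design["fence"] == 0)]
        traits = pd.DataFrame(
            {
                "plot_id": ctrl["plot_id"].tolist(),
                "species": "A",
                "replicate": 1,
                "trait": "SLA",
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        out = tp.reference_species_means(traits, design)
        assert out["reference_mean"].iloc[0] == pytest.approx(2.5)
        assert out["provenance"].iloc[0] == "control"

    def test_ambient_fallback_for_fence_only_species(self):
        design = self._design()
        fence_only = design[(design["nutrient"] == 0) & (design["fence"] == 1)]
        traits = pd.DataFrame(
            {
                "plot_id": fence_only["plot_id"].tolist(),
                "species": "B",
                "replicate": 1,
                "trait": "SLA",
                "value": [7.0, 9.0, 8.0, 8.0],
            }
        )
        out = tp.reference_species_means(traits, design)
        assert out["provenance"].iloc[0] == "ambient_fallback"
        assert out["reference_mean"].iloc[0] == pytest.approx(8.0)

    def test_site_fallback_and_single_measurement(self):
        design = self._design()
        nut = design[design["nutrient"] == 1]["plot_id"].iloc[0]
        traits = pd.DataFrame(
            {"plot_id": [nut], "species": "C", "replicate": 1,
             "trait": "SLA", "value": [3.3]}
        )
        out = tp.reference_species_means(traits, design)
        assert out["provenance"].iloc[0] == "site_fallback"
        assert out["reference_mean"].iloc[0] == pytest.approx(3.3)

    def test_unknown_plot_raises(self):
        design = self._design()
        traits = pd.DataFrame(
            {"plot_id": ["ghost"], "species": "A", "replicate": 1,
             "trait": "SLA", "value": [1.0]}
        )
        with pytest.raises(ValueError, match="ghost"):
            tp.reference_species_means(traits, design)


class TestFixedCwmAndItv:
    def test_fixed_equals_bootstrap_on_reference_table(self):
        """Replacing the per-plot trait table by the reference table makes
        bootstrap_cwm and fixed_cwm identical under the same seed."""
        design = tp.generate_design(1, 2, seed=0)
        plots = design["plot_id"].tolist()
        covers = pd.DataFrame(
            [(p, sp, c) for p in plots for sp, c in (("A", 60.0), ("B", 40.0))],
            columns=["plot_id", "species", "cover"],
        )
        refs = pd.DataFrame(
            {
                "site": design["site"].iloc[0],
                "species": ["A", "B"],
                "trait": "SLA",
                "reference_mean": [12.0, 4.0],
                "provenance": "control",
            }
        )
        ref_as_traits = pd.DataFrame(
            [(p, sp, 1, "SLA", v) for p in plots
             for sp, v in (("A", 12.0), ("B", 4.0))],
            columns=["plot_id", "species", "replicate", "trait", "value"],
        )
        a = tp.bootstrap_cwm(ref_as_traits, covers, seed=9)
        b = tp.fixed_cwm(refs, covers, design, seed=9)
        assert np.allclose(a["value"].to_numpy(), b["value"].to_numpy())

    def test_constant_reference_gives_constant_fixed_cwm(self):
        design = tp.generate_design(1, 2, seed=0)
        plots = design["plot_id"].tolist()
        covers = pd.DataFrame(
            [(p, sp, c) for p in plots for sp, c in (("A", 30.0), ("B", 70.0))],
            columns=["plot_id", "species", "cover"],
        )
        refs = pd.DataFrame(
            {"site": design["site"].iloc[0], "species": ["A", "B"],
             "trait": "SLA", "reference_mean": [6.0, 6.0], "provenance": "control"}
        )
        out = tp.fixed_cwm(refs, covers, design, seed=2)
        assert np.allclose(out["value"], 6.0)

    def test_itv_is_exact_difference_and_key_mismatch_raises(self):
        spec = pd.DataFrame(
            {"plot_id": ["p1", "p2"], "trait": "SLA", "component": "specific",
             "value": [9.5, 8.0], "bootstrap_se": 0.1}
        )
        fixed = spec.assign(component="fixed", value=[8.0, 8.0])
        itv = tp.itv_component(spec, fixed)
        assert itv["value"].tolist() == [1.5, 0.0]
        with pytest.raises(ValueError, match="p2"):
            tp.itv_component(spec, fixed.iloc[:1])

    def test_itv_identity_machine_precision(self, cwm_tables):
        wide = cwm_tables.pivot(
            index=["plot_id", "trait"], columns="component", values="value"
        ).dropna()
        assert np.allclose(
            wide["itv"], wide["specific"] - wide["fixed"], atol=1e-12, rtol=0
        )

    def test_zero_itv_community_gives_zero_itv_component(self):
        """No ITV effects, no block or measurement noise: specific and fixed
        CWM bootstraps see identical values, so ITV vanishes exactly."""
        design = tp.generate_design(1, 4, seed=3)
        params = tp.SimulationParams(
            seed=3, itv_effect={},
            trait_sd_within={t: 0.0 for t in tp.TRAITS},
            block_sd={t: 0.0 for t in tp.TRAITS},
        )
        cover, traits, _, _ = tp.generate_community(design, params)
        cover_dom = tp.filter_dominant(cover)
        spec = tp.bootstrap_cwm(traits, cover_dom, seed=5)
        refs = tp.reference_species_means(traits, design)
        fixed = tp.fixed_cwm(refs, cover_dom, design, seed=5)
        itv = tp.itv_component(spec, fixed)
        se = spec.set_index(["plot_id", "trait"])["bootstrap_se"]
        sef = fixed.set_index(["plot_id", "trait"])["bootstrap_se"]
        for r in itv.itertuples(index=False):
            bound = 2.0 * (se[(r.plot_id, r.trait)] + sef[(r.plot_id, r.trait)])
            assert abs(r.value) <= max(bound, 1e-9)


def test_dominance_restriction_bounds_cwm_shift(community, design):
    """Dropping <20% relative cover of subordinate species moves the CWM by
    less than the dominant species' trait range (smoke property)."""
    cover, traits, _, truth = community
    full = truth.realized_species_plot_means
    plot = design["plot_id"].iloc[0]
    sub = cover[cover["plot_id"] == plot]
    dom = tp.select_dominant_species(zip(sub["species"], sub["cover"]), 0.8)
    m = full[(full["plot_id"] == plot) & (full["trait"] == "SLA")]
    m = m.set_index("species")["mean"]
    w = sub.set_index("species")["cover"]
    cwm_all = float((w * m).sum() / w.sum())
    wd = w.loc[dom]
    cwm_dom = float((wd * m.loc[dom]).sum() / wd.sum())
    assert abs(cwm_all - cwm_dom) <= (m.max() - m.min())
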