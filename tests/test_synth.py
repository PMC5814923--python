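"""Generator behaviour: determinism, field structure, kernels, contaminants."""

import numpy as np
import pandas as pd
import pytest

from hydroniche import (
    ContaminationSpec,
    FieldSpec,
    GridGeometry,
    ClimateStack,
    LandscapeSpec,
    NicheSpec,
    generate_climate_stack,
    generate_species_occurrences,
    inject_contaminants,
    native_boxes_from_occurrences,
)
from hydroniche.synth import _default_fields


def test_same_spec_same_seed_gives_identical_stacks():
    spec = LandscapeSpec(seed=42)
    a, b = generate_climate_stack(spec), generate_climate_stack(spec)
    for name in a.layers:
        np.testing.assert_array_equal(a[name], b[name])


def test_different_seed_changes_fields():
    a = generate_climate_stack(LandscapeSpec(seed=1))
    b = generate_climate_stack(LandscapeSpec(seed=2))
    assert not np.array_equal(a["MAP"], b["MAP"])


def test_zero_amplitude_yields_constant_layer():
    fields = _default_fields()
    fields["MAP"] = FieldSpec(1200.0, 0.0, 6.0, 0.0, 8000.0)
    stack = generate_climate_stack(LandscapeSpec(fields=fields, seed=3))
    np.testing.assert_array_equal(stack["MAP"], np.full(stack["MAP"].shape, 1200.0))


def test_ai_layer_matches_cellwise_recomputation():
    """AI must equal round(1e4 * MAP / PET) cell by cell, with nodata at PET=0."""
    fields = _default_fields()
    fields["PET"] = FieldSpec(300.0, 300.0, 4.0, 0.0, 600.0)  # allows PET = 0 cells
    stack = generate_climate_stack(LandscapeSpec(fields=fields, seed=9))
    pet, m, ai = stack["PET"], stack["MAP"], stack["AI"]
    nd = stack.nodata["AI"]
    for i in range(0, stack.geometry.n_rows, 7):
        for j in range(0, stack.geometry.n_cols, 7):
            if pet[i, j] == 0:
                assert ai[i, j] == nd
            else:
                assert ai[i, j] == round(1e4 * m[i, j] / pet[i, j])
    ok = pet > 0
    np.testing.assert_array_equal(ai[ok], np.round(1e4 * m[ok] / pet[ok]))
    assert np.all(ai[~ok] == nd)


def test_cross_block_correlation_near_zero_when_requested():
    spec = LandscapeSpec(seed=3, cross_block_correlation=0.0, n_cols=150, n_rows=100)
    stack = generate_climate_stack(spec)
    assert stack["MAP"].size >= 10_000
    c = np.corrcoef(stack["MAP"].ravel(), stack["P_seas"].ravel())[0, 1]
    assert abs(c) <= 0.15


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_cols": 1},
        {"cell_size": 0.0},
        {"cross_block_correlation": 1.5},
        {"own_noise_weight": 1.0},
    ],
)
def test_invalid_landscape_spec_rejected(kwargs):
    with pytest.raises(ValueError):
        LandscapeSpec(**kwargs)


def test_invalid_field_spec_rejected():
    with pytest.raises(ValueError):
        FieldSpec(100.0, 10.0, 2.0, clamp_min=50.0, clamp_max=10.0)


# --------------------------------------------------------------------- niches


def _ramp_stack(n=40, vmin=0.0, vmax=3900.0):
    """MAP varies linearly across columns (uniform value density)."""
    geom = GridGeometry(origin_lon=-70.0, origin_lat=0.0, cell_size=0.1, n_cols=n, n_rows=n)
    col_vals = np.linspace(vmin, vmax, n)
    layers = {
        "MAP": np.tile(col_vals, (n, 1)),
        "P_dry": np.full((n, n), 50.0),
        "P_seas": np.full((n, n), 60.0),
        "AET": np.full((n, n), 1000.0),
        "PET": np.full((n, n), 1500.0),
    }
    layers["AI"] = np.round(1e4 * layers["MAP"] / layers["PET"])
    return ClimateStack(geometry=geom, layers=layers)


def test_seeded_occurrences_are_reproducible(stack):
    niches = [NicheSpec("dup", {"MAP": 1500.0}, {"MAP": 300.0}, n_points=30)]
    a, _ = generate_species_occurrences(stack, niches, seed=4)
    b, _ = generate_species_occurrences(stack, niches, seed=4)
    pd.testing.assert_frame_equal(a, b)


def test_occurrences_independent_of_species_insertion_order(stack):
    n1 = NicheSpec("alpha", {"MAP": 1200.0}, {"MAP": 250.0}, n_points=25)
    n2 = NicheSpec("beta", {"MAP": 2000.0}, {"MAP": 250.0}, n_points=25)
    fwd, _ = generate_species_occurrences(stack, [n1, n2], seed=8)
    rev, _ = generate_species_occurrences(stack, [n2, n1], seed=8)
    fwd = fwd.sort_values("record_id").reset_index(drop=True)
    rev = rev.sort_values("record_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(fwd, rev)


def test_tiny_breadth_samples_only_cells_closest_to_optimum():
    stack = _ramp_stack()
    opt = 2017.0
    niches = [NicheSpec("narrow", {"MAP": opt}, {"MAP": 1e-3 * 3900.0}, n_points=200)]
    occ, _ = generate_species_occurrences(stack, niches, seed=0)
    row, col = stack.geometry.cell_index(
        occ["longitude"].to_numpy(), occ["latitude"].to_numpy()
    )
    sampled_vals = stack["MAP"][row, col]
    closest = stack["MAP"].ravel()[np.argmin(np.abs(stack["MAP"].ravel() - opt))]
    assert set(np.unique(sampled_vals)) == {closest}


def test_kernel_mean_converges_to_optimum_on_uniform_density():
    """On a value-uniform landscape the sampled mean matches the optimum."""
    stack = _ramp_stack()
    opt, sigma, n = 1950.0, 300.0, 1000
    occ, _ = generate_species_occurrences(
        stack, [NicheSpec("conv", {"MAP": opt}, {"MAP": sigma}, n_points=n)], seed=1
    )
    row, col = stack.geometry.cell_index(
        occ["longitude"].to_numpy(), occ["latitude"].to_numpy()
    )
    vals = stack["MAP"][row, col]
    se = vals.std(ddof=1) / np.sqrt(n)
    assert abs(vals.mean() - opt) <= 2 * se


def test_sampled_mean_matches_kernel_weighted_population_mean(stack):
    """Sharper sampler check: the sampling distribution's own mean."""
    opt, sigma, n = 1500.0, 200.0, 2000
    occ, _ = generate_species_occurrences(
        stack, [NicheSpec("pop", {"MAP": opt}, {"MAP": sigma}, n_points=n)], seed=6
    )
    row, col = stack.geometry.cell_index(
        occ["longitude"].to_numpy(), occ["latitude"].to_numpy()
    )
    vals = stack["MAP"][row, col]
    v = stack["MAP"].ravel()
    w = np.exp(-((v - opt) ** 2) / (2 * sigma**2))
    pop_mean = np.sum(w * v) / np.sum(w)
    se = vals.std(ddof=1) / np.sqrt(n)
    assert abs(vals.mean() - pop_mean) <= 3 * se


def test_zero_mass_kernel_raises_listing_species(stack):
    niches = [NicheSpec("ghost", {"MAP": 1e9}, {"MAP": 1.0}, n_points=5)]
    with pytest.raises(ValueError, match="ghost"):
        generate_species_occurrences(stack, niches, seed=0)


def test_optima_and_breadths_recorded_in_truth_table(stack):
    niches = [NicheSpec("t1", {"MAP": 1111.0, "P_seas": 44.0}, {"MAP": 222.0, "P_seas": 9.0})]
    _, truth = generate_species_occurrences(stack, niches, seed=0)
    row = truth.iloc[0]
    assert row["MAP_optimum"] == 1111.0 and row["MAP_breadth"] == 222.0
    assert row["P_seas_optimum"] == 44.0 and row["P_seas_breadth"] == 9.0


# --------------------------------------------------------------- contaminants


def test_zero_contamination_is_identity(cohort):
    occ, _ = cohort
    boxes = native_boxes_from_occurrences(occ)
    out = inject_contaminants(occ, boxes, ContaminationSpec())
    assert (out["label"] == "clean").all()
    pd.testing.assert_frame_equal(out.drop(columns="label"), occ)


def test_duplicate_counting_on_five_record_species():
    occ = pd.DataFrame(
        {
            "species": "solo",
            "longitude": np.linspace(-60, -59, 5),
            "latitude": np.linspace(-10, -9, 5),
            "record_id": [f"solo_{i}" for i in range(5)],
        }
    )
    boxes = native_boxes_from_occurrences(occ)
    out = inject_contaminants(occ, boxes, ContaminationSpec(n_duplicates=2))
    assert len(out) == 7
    assert (out["label"] == "duplicate").sum() == 2


def test_label_counts_match_spec_per_species(cohort):
    occ, _ = cohort
    boxes = native_boxes_from_occurrences(occ)
    spec = ContaminationSpec(
        n_duplicates=3,
        institution_points=((-60.0, -30.0),),
        n_institution=2,
        n_out_of_range=1,
        seed=7,
    )
    out = inject_contaminants(occ, boxes, spec)
    for _, grp in out.groupby("species"):
        counts = grp["label"].value_counts()
        assert counts.get("duplicate", 0) == 3
        assert counts.get("institution", 0) == 2
        assert counts.get("out_of_range", 0) == 1
    # out-of-range records really are outside the native box
    b = boxes.set_index("species")
    oor = out[out["label"] == "out_of_range"]
    for _, r in oor.iterrows():
        box = b.loc[r["species"]]
        assert not (box["lon_min"] <= r["longitude"] <= box["lon_max"])


def test_contamination_requires_native_box():
    occ = pd.DataFrame(
        {"species": "x", "longitude": [-60.0], "latitude": [-10.0], "record_id": ["x_0"]}
    )
    empty_boxes = pd.DataFrame(columns=["species", "lon_min", "lon_max", "lat_min", "lat_max"])
    with pytest.raises(ValueError, match="native box"):
        inject_contaminants(occ, empty_boxes, ContaminationSpec(n_out_of_range=1))


def test_invalid_contamination_spec_rejected():
    with pytest.raises(ValueError):
        ContaminationSpec(n_duplicates=-1)
    with pytest.raises(ValueError):
        ContaminationSpec(n_institution=1)  # no institution points given
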