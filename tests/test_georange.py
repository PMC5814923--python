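"""Convex hulls in lon/lat and geodesic polygon areas on WGS84."""

import math

import numpy as np
import pandas as pd
import pytest

from hydroniche import convex_hull, ellipsoidal_area, species_georanges

# Independent oracle constants: authalic sphere radius of WGS84 (km) and
# first eccentricity squared, entered from standard reference values
# rather than derived from the implementation's code path.
ORACLE_R_KM = 6371.0071809
ORACLE_E2 = 0.00669437999014


def _oracle_authalic_lat(phi):
    """Series expansion for geodetic -> authalic latitude (radians)."""
    e2 = ORACLE_E2
    c2 = -(e2 / 3 + 31 * e2**2 / 180 + 59 * e2**3 / 560)
    c4 = 17 * e2**2 / 360 + 61 * e2**3 / 1260
    c6 = -383 * e2**3 / 45360
    return phi + c2 * math.sin(2 * phi) + c4 * math.sin(4 * phi) + c6 * math.sin(6 * phi)


def _lhuilier_area_km2(ring):
    """Spherical-excess polygon area by l'Huilier triangulation."""
    pts = ring[:-1] if np.allclose(ring[0], ring[-1]) else ring
    vecs = []
    for lon, lat in pts:
        lam, beta = math.radians(lon), _oracle_authalic_lat(math.radians(lat))
        vecs.append(
            np.array(
                [
                    math.cos(beta) * math.cos(lam),
                    math.cos(beta) * math.sin(lam),
                    math.sin(beta),
                ]
            )
        )

    def arc(u, v):
        return math.acos(max(-1.0, min(1.0, float(np.dot(u, v)))))

    total = 0.0
    for i in range(1, len(vecs) - 1):
        a = arc(vecs[0], vecs[i])
        b = arc(vecs[i], vecs[i + 1])
        c = arc(vecs[i + 1], vecs[0])
        s = (a + b + c) / 2.0
        t = math.tan(s / 2) * math.tan((s - a) / 2) * math.tan((s - b) / 2) * math.tan((s - c) / 2)
        total += 4.0 * math.atan(math.sqrt(max(0.0, t)))
    return total * ORACLE_R_KM**2


def _gift_wrap(points):
    """Independent hull oracle: Jarvis march, returns vertex set."""
    pts = [tuple(p) for p in np.unique(np.asarray(points, float), axis=0)]
    if len(pts) < 3:
        return set()
    start = min(pts)
    hull, p = [], start
    while True:
        hull.append(p)
        q = pts[0] if pts[0] != p else pts[1]
        for r in pts:
            if r == p:
                continue
            cross = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
            if q == p or cross < 0 or (
                cross == 0
                and (r[0] - p[0]) ** 2 + (r[1] - p[1]) ** 2
                > (q[0] - p[0]) ** 2 + (q[1] - p[1]) ** 2
            ):
                q = r
        p = q
        if p == start:
            break
    return set(hull)


def test_interior_point_excluded_from_hull():
    pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
    ring, degenerate = convex_hull(pts)
    assert not degenerate
    assert len(ring) == 5  # 4 vertices + closing repeat
    assert (0.5, 0.5) not in {tuple(v) for v in ring}
    np.testing.assert_array_equal(ring[0], ring[-1])


def test_collinear_points_are_degenerate():
    ring, degenerate = convex_hull(np.array([[0, 0], [1, 1], [2, 2]]))
    assert degenerate and ring.size == 0
    assert ellipsoidal_area(ring) == 0.0


def test_hull_is_counter_clockwise():
    ring, _ = convex_hull(np.array([[0, 0], [2, 0], [2, 2], [0, 2]]))
    shoelace = sum(
        ring[i, 0] * ring[i + 1, 1] - ring[i + 1, 0] * ring[i, 1]
        for i in range(len(ring) - 1)
    )
    assert shoelace > 0


def test_hull_matches_gift_wrapping_oracle():
    rng = np.random.default_rng(11)
    for _ in range(25):
        pts = rng.uniform((-70, -20), (-60, -10), size=(20, 2))
        ring, degenerate = convex_hull(pts)
        assert not degenerate
        assert {tuple(v) for v in ring[:-1]} == _gift_wrap(pts)


def test_out_of_bounds_coordinates_rejected():
    with pytest.raises(ValueError, match="bounds"):
        convex_hull(np.array([[200.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


def test_equatorial_quad_matches_spherical_excess_oracle():
    ring, _ = convex_hull(np.array([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]]))
    area = ellipsoidal_area(ring)
    oracle = _lhuilier_area_km2(ring)
    assert area == pytest.approx(oracle, rel=0.005)


def test_midlatitude_polygon_matches_oracle():
    ring, _ = convex_hull(
        np.array([[-71.0, -33.0], [-69.5, -33.4], [-69.2, -31.8], [-70.8, -31.5], [-70.1, -32.5]])
    )
    assert ellipsoidal_area(ring) == pytest.approx(_lhuilier_area_km2(ring), rel=0.005)


def test_area_invariant_under_ring_rotation():
    ring, _ = convex_hull(np.array([[-70, -15], [-68, -15], [-68, -13], [-70, -13]]))
    open_ring = ring[:-1]
    base = ellipsoidal_area(ring)
    for k in range(1, len(open_ring)):
        rolled = np.roll(open_ring, k, axis=0)
        closed = np.vstack([rolled, rolled[:1]])
        assert ellipsoidal_area(closed) == pytest.approx(base, rel=1e-12)


def test_small_polygon_agrees_with_planar_scaling():
    """For hulls under 2 degrees the flat-earth shoelace with cos(lat)
    longitude scaling must agree within 2%."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        lat0 = rng.uniform(-40, 40)
        pts = rng.uniform((-60, lat0), (-58.5, lat0 + 1.5), size=(15, 2))
        ring, degenerate = convex_hull(pts)
        if degenerate:
            continue
        deg_km = math.pi / 180.0 * ORACLE_R_KM
        x = ring[:, 0] * deg_km * math.cos(math.radians(pts[:, 1].mean()))
        y = ring[:, 1] * deg_km
        planar = 0.5 * abs(
            sum(x[i] * y[i + 1] - x[i + 1] * y[i] for i in range(len(ring) - 1))
        )
        assert ellipsoidal_area(ring) == pytest.approx(planar, rel=0.02)


def test_adding_outside_point_never_decreases_area():
    rng = np.random.default_rng(9)
    pts = rng.uniform((-65, -18), (-63, -16), size=(12, 2))
    ring, _ = convex_hull(pts)
    base = ellipsoidal_area(ring)
    grown_ring, _ = convex_hull(np.vstack([pts, [-60.0, -15.0]]))
    assert ellipsoidal_area(grown_ring) >= base


def test_antimeridian_spanning_ring_rejected():
    ring = np.array([[-170.0, 0.0], [170.0, 0.0], [170.0, 5.0], [-170.0, 5.0], [-170.0, 0.0]])
    with pytest.raises(ValueError, match="antimeridian"):
        ellipsoidal_area(ring)


def test_species_georanges_table_and_degenerate_flag():
    records = pd.DataFrame(
        {
            "species": ["a"] * 4 + ["b"] * 3,
            "longitude": [-70, -69, -69, -70, -60, -59, -58],
            "latitude": [-15, -15, -14, -14, -10, -9, -8],
            "record_id": [f"r{i}" for i in range(7)],
        }
    )
    out = species_georanges(records)
    a = out[out["species"] == "a"].iloc[0]
    b = out[out["species"] == "b"].iloc[0]  # collinear points
    assert a["area_km2"] > 0 and not a["degenerate"]
    assert b["area_km2"] == 0.0 and b["degenerate"]
    assert (out["area_km2"] == 0).equals(out["degenerate"])
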