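import numpy as np
import pandas as pd
import pytest

from reefscape.grid import Grid, build_dem_set, crop_to_reefs
from reefscape.occurrence import build_feature_table, sample_background, thin_occurrences
from reefscape.synth import ReefSpec, ResponseSpec, generate_reef_dem, simulate_occurrences
from reefscape.terrain import derive_all, layer_name


def make_grid(values, px=1.0, crs="TEST", source="SYNTH", mask=None):
    values = np.asarray(values, dtype=float)
    return Grid(values=values, transform=(0.0, values.shape[0] * px, px),
                crs_id=crs, nodata_mask=mask, source_tag=source)


def plane_grid(nr, nc, gx=0.0, gy=0.0, c=0.0, px=1.0):
    """z = gx*x + gy*y + c evaluated at cell centres (y up, x east)."""
    xs = (np.arange(nc) + 0.5) * px
    ys = nr * px - (np.arange(nr) + 0.5) * px
    X, Y = np.meshgrid(xs, ys)
    return make_grid(gx * X + gy * Y + c, px=px)


@pytest.fixture(scope="session")
def reef_world():
    """Default synthetic world shared by read-only tests."""
    spec = ReefSpec(seed=11)
    aca15, dr30, dr100, reefs, truth = generate_reef_dem(spec)
    return {"spec": spec, "aca15": aca15, "dr30": dr30, "dr100": dr100,
            "reefs": reefs, "truth": truth}


@pytest.fixture(scope="session")
def dem_stack(reef_world):
    return build_dem_set(reef_world["aca15"], reef_world["dr30"], reef_world["dr100"])


@pytest.fixture(scope="session")
def variables(dem_stack):
    return derive_all(dem_stack)


def make_recovery_fixture(seed, n_presence=250, n_background=1500):
    """Strong-signal world: occurrences driven by SLOPE and BPI, plus two
    pure-noise predictor layers; background drawn from the same shallow band.

    Returns (feature_table, base_column_names, generating, noise).
    """
    spec = ReefSpec(seed=seed, roughness_sd_m=1.5, noise_sd_m=0.05)
    aca15, dr30, dr100, reefs, truth = generate_reef_dem(spec)
    stack = build_dem_set(aca15, dr30, dr100)
    variables = derive_all(stack)
    slope_key = layer_name(("ACA", 15, "SLOPE"))
    bpi_key = layer_name(("ACA", 15, "BPI"))
    resp = ResponseSpec(coefficients={slope_key: 3.0, bpi_key: 2.5},
                        intercept=-5.0, n_presence=n_presence, gps_noise_sd_m=0.0)
    presences, coords, _records, _tides = simulate_occurrences(
        variables, resp, reefs, seed=seed + 100, truth=truth)
    ref = stack[("ACA", 15)]
    shallow_mask = ref.nodata_mask | (ref.values < -resp.depth_cap_m) | (ref.values >= 0)
    shallow = Grid(values=np.where(shallow_mask, np.nan, ref.values),
                   transform=ref.transform, crs_id=ref.crs_id,
                   nodata_mask=shallow_mask, source_tag=ref.source_tag)
    thinned = thin_occurrences(presences, ref)
    crops = crop_to_reefs(shallow, reefs)
    background = sample_background(coords, crops, n=n_background, seed=seed + 200,
                                   bias_bandwidth_m=np.inf)
    rng = np.random.default_rng(seed + 300)
    noise_keys = []
    for i in (1, 2):
        key = ("ACA", 15, f"NOISE{i}")
        variables.layers[key] = ref.with_values(rng.normal(size=ref.shape))
        noise_keys.append(layer_name(key))
    keys = [("ACA", 15, "SLOPE"), ("ACA", 15, "BPI"),
            ("ACA", 15, "NOISE1"), ("ACA", 15, "NOISE2")]
    table = build_feature_table(thinned, background, variables, keys)
    return table, [layer_name(k) for k in keys], [slope_key, bpi_key], noise_keys


@pytest.fixture(scope="session")
def recovery_fixture():
    return make_recovery_fixture(seed=0)
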