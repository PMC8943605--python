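import numpy as np
import pytest

import simsfilter as sf


@pytest.fixture(scope="session")
def serum_constraints() -> sf.SearchConstraints:
    """Positive-mode protein-fragment element box used on serum-like data."""
    return sf.SearchConstraints(
        ranges=(
            sf.ElementRange("C", 4, 100),
            sf.ElementRange("H", 8, 200),
            sf.ElementRange("N", 0, 20),
            sf.ElementRange("O", 0, 20),
            sf.ElementRange("S", 0, 1),
            sf.ElementRange("Na", 0, 1),
        ),
        tolerance=sf.TolerancePolicy.constant(2.0),
        charge=+1,
    )


@pytest.fixture(scope="session")
def two_component_scenario():
    """The bundled two-component scenario, loaded once per session."""
    return sf.load_scenario(sf.bundled_scenario_path())


@pytest.fixture()
def three_peak_fixture():
    """Three peaks built from known ion m/z: two inside a small CHOS box,
    one (an inorganic chloride cluster) outside it."""
    inside = [sf.parse_formula("C16H31O2"), sf.parse_formula("C8H7SO3")]
    outside = sf.parse_formula("Na2Cl")
    peaks = [
        sf.Peak(id=f"p{i}", mz=sf.ion_mz(f, -1), total_intensity=100.0)
        for i, f in enumerate(inside + [outside])
    ]
    pl = sf.PeakList(peaks=peaks, polarity="negative")
    constraints = sf.SearchConstraints(
        ranges=(
            sf.ElementRange("C", 0, 20),
            sf.ElementRange("H", 0, 40),
            sf.ElementRange("O", 0, 4),
            sf.ElementRange("S", 0, 1),
        ),
        tolerance=sf.TolerancePolicy.constant(2.0),
        charge=-1,
    )
    return pl, constraints, inside


def random_box(rng: np.random.Generator, max_combos: int = 100_000):
    """A random small constraint box (<= max_combos Cartesian points) and a
    random m/z near a mass reachable inside it."""
    symbols = ["C", "H", "N", "O", "S", "Na", "P", "Cl"]
    n_elem = rng.integers(2, 5)
    chosen = list(rng.choice(symbols, size=n_elem, replace=False))
    ranges, combos = [], 1
    for sym in chosen:
        lo = int(rng.integers(0, 3))
        span = int(rng.integers(1, 12))
        hi = lo + span
        while combos * (span + 1) > max_combos:
            span = max(span // 2, 1)
            hi = lo + span
            if combos * (span + 1) <= max_combos or span == 1:
                break
        combos *= hi - lo + 1
        ranges.append(sf.ElementRange(sym, lo, hi))
    # aim at a mass realizable inside the box so hits are common
    mass = sum(
        sf.DEFAULT_ELEMENTS.mass(r.symbol)
        * int(rng.integers(r.min_count, r.max_count + 1))
        for r in ranges
    )
    if mass <= 0:
        mass = 50.0
    mz = mass * (1 + rng.normal(0, 2e-6))
    tol = float(rng.choice([2.0, 5.0, 20.0]))
    charge = int(rng.choice([-1, 0, 1]))
    constraints = sf.SearchConstraints(
        ranges=tuple(ranges),
        tolerance=sf.TolerancePolicy.constant(tol),
        charge=charge,
    )
    return max(mz, 1.0), constraints
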