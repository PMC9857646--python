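"""Series readers/writers and the packaged synthetic fixture.

Series live in plain text (one integer per line) or single-column CSV with a
``value`` header.  The range limit n is always explicit user input: the
observed maximum of a series may undershoot the true structural range, so it
is never inferred from the data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .process import CMPBARParams, CountSeries, simulate

#: CMPBAR(1) parameters of the packaged synthetic fixture: a weekly-count
#: regime on n = 7 (e.g. rainy days per week) with mild over-dispersion.
FIXTURE_PARAMS = CMPBARParams(n=7, theta1=1.2313, theta2=0.9547, nu=0.0995)
FIXTURE_T = 312  # 313 observations, six years of weeks


def read_series(path: str | Path, n: int) -> CountSeries:
    """Read a count series from plain text or single-column CSV.

    A ``value`` header line is accepted and skipped; any non-integer token or
    out-of-range value raises with the offending line number.
    """
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip().rstrip(",")
            if not tok:
                continue
            if lineno == 1 and tok.lower() == "value":
                continue
            try:
                v = int(tok)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer token {tok!r}"
                ) from None
            if not 0 <= v <= n:
                raise ValueError(
                    f"{path}:{lineno}: value {v} outside {{0..{n}}}"
                )
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no values found")
    return CountSeries(values=np.array(values, dtype=np.int64), n=n)


def write_series(series: CountSeries, path: str | Path, csv: bool | None = None) -> None:
    """Write one integer per line; CSV adds a ``value`` header."""
    path = Path(path)
    if csv is None:
        csv = path.suffix.lower() == ".csv"
    with open(path, "w") as fh:
        if csv:
            fh.write("value\n")
        fh.writelines(f"{int(v)}\n" for v in series.values)


def generate_fixture(
    kind: str = "weekly-overdispersed",
    params: CMPBARParams | None = None,
    T: int | None = None,
    seed: int = 20230107,
) -> tuple[CountSeries, dict]:
    """Reproducible synthetic series plus metadata.

    The default fixture is a synthetic stand-in emulating a weekly rainy-day
    regime: n = 7, 313 observations, parameters in the mildly over-dispersed
    region (nu well below 1), so its sample BID typically lands above 1.
    """
    if kind != "weekly-overdispersed":
        raise ValueError(f"unknown fixture kind {kind!r}")
    if params is None:
        params = FIXTURE_PARAMS
    if T is None:
        T = FIXTURE_T
    rng = np.random.default_rng(seed)
    series = simulate(params, T, rng, x0="stationary")
    meta = {
        "kind": kind,
        "synthetic": True,
        "n": params.n,
        "theta1": params.theta1,
        "theta2": params.theta2,
        "nu": params.nu,
        "T": T,
        "seed": seed,
    }
    return series, meta


def sample_bid(series: CountSeries) -> float:
    """Sample binomial index of dispersion n * s^2 / (xbar (n - xbar))."""
    x = series.values.astype(float)
    mean = x.mean()
    var = x.var(ddof=1)
    return float(series.n * var / (mean * (series.n - mean)))


def dump_json(obj: dict, path: str | Path) -> None:
    """JSON with floats at 17 significant digits for reproducible comparison."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
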