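"""Packaged default parameter values and flat-config (de)serialisation.

The constants below are the published calibration of the model shipped
as package defaults: the exponential entry-age intensities (one per
entry age E = 0, 30, 60, obtained upstream by regressing logarithmic UN
cohort counts on the year -- re-deriving them from UN data is outside
the scope of this package) and the maximum-likelihood gamma-Gompertz
trend parameters for the fixed rates of aging b = 0.09 (the reference
fit) and b = 0.11, 0.13, 0.15 (the sensitivity rows).  Users with their
own data can refit everything via :mod:`recordage.likelihood` and
:func:`recordage.intensity.fit_exponential_intensity`.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .distributions import LifespanLaw, MortalityTrend
from .intensity import BirthIntensity

#: Entry-age cohort intensities lambda_E(t) = C_E exp(kappa_E t).
BIRTH_INTENSITIES = {
    0: BirthIntensity(C=6270.0, kappa=0.004987, entry_age=0.0),
    30: BirthIntensity(C=4.680e-9, kappa=0.01876, entry_age=30.0),
    60: BirthIntensity(C=3.249e-11, kappa=0.02085, entry_age=60.0),
}

#: Fitted GG trend parameters keyed by (entry age, rate of aging b).
MORTALITY_TRENDS = {
    (0, 0.09): MortalityTrend(K=2.951e-5, alpha=0.01277, b=0.09, gamma=0.08596, entry_age=0.0),
    (30, 0.09): MortalityTrend(K=5.950e-4, alpha=0.01124, b=0.09, gamma=0.08061, entry_age=30.0),
    (60, 0.09): MortalityTrend(K=1.208e-2, alpha=0.01110, b=0.09, gamma=0.08026, entry_age=60.0),
    (0, 0.11): MortalityTrend(K=3.728e-6, alpha=0.01561, b=0.11, gamma=0.1160, entry_age=0.0),
    (30, 0.11): MortalityTrend(K=1.495e-4, alpha=0.01376, b=0.11, gamma=0.1117, entry_age=30.0),
    (60, 0.11): MortalityTrend(K=5.901e-3, alpha=0.01352, b=0.11, gamma=0.1110, entry_age=60.0),
    (0, 0.13): MortalityTrend(K=4.530e-7, alpha=0.01845, b=0.13, gamma=0.1441, entry_age=0.0),
    (30, 0.13): MortalityTrend(K=3.613e-5, alpha=0.01628, b=0.13, gamma=0.14065, entry_age=30.0),
    (60, 0.13): MortalityTrend(K=2.784e-3, alpha=0.01596, b=0.13, gamma=0.1399, entry_age=60.0),
    (0, 0.15): MortalityTrend(K=5.362e-8, alpha=0.02129, b=0.15, gamma=0.1708, entry_age=0.0),
    (30, 0.15): MortalityTrend(K=8.500e-6, alpha=0.01880, b=0.15, gamma=0.1681, entry_age=30.0),
    (60, 0.15): MortalityTrend(K=1.281e-3, alpha=0.01842, b=0.15, gamma=0.1674, entry_age=60.0),
}

#: Trend refitted on titleholder data truncated at 1988 (backtest), E=0, b=0.09.
BACKTEST_TREND_1988 = MortalityTrend(
    K=2.064e-5, alpha=0.01516, b=0.09, gamma=0.08413, entry_age=0.0
)


def default_process(entry_age: int = 0, b: float = 0.09, x_max: float = 150.0):
    """Record-age process with the packaged default calibration."""
    from .process import RecordAgeProcess

    try:
        intensity = BIRTH_INTENSITIES[entry_age]
        trend = MORTALITY_TRENDS[(entry_age, b)]
    except KeyError as exc:
        raise KeyError(
            f"no packaged calibration for entry_age={entry_age}, b={b}; "
            "construct BirthIntensity/MortalityTrend directly"
        ) from exc
    return RecordAgeProcess(intensity=intensity, trend=trend, x_max=x_max)


# -- flat config ------------------------------------------------------

_CONFIG_KEYS = ("E", "C", "kappa", "K", "alpha", "b", "gamma", "c")


def spec_to_dict(intensity: BirthIntensity, trend: MortalityTrend) -> dict:
    """Flatten an intensity/trend pair to the config key set."""
    if intensity.entry_age != trend.entry_age:
        raise ValueError("intensity and trend disagree on the entry age")
    return {
        "E": intensity.entry_age,
        "C": intensity.C,
        "kappa": intensity.kappa,
        "K": trend.K,
        "alpha": trend.alpha,
        "b": trend.b,
        "gamma": trend.gamma,
        "c": trend.c,
    }


def spec_from_dict(d: dict) -> tuple[BirthIntensity, MortalityTrend]:
    """Inverse of :func:`spec_to_dict`; unknown keys are rejected."""
    unknown = set(d) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    E = float(d.get("E", 0.0))
    intensity = BirthIntensity(C=float(d["C"]), kappa=float(d["kappa"]), entry_age=E)
    trend = MortalityTrend(
        K=float(d["K"]),
        alpha=float(d["alpha"]),
        b=float(d["b"]),
        gamma=float(d["gamma"]),
        entry_age=E,
        c=float(d.get("c", 0.0)),
    )
    return intensity, trend


def load_config(path) -> dict:
    """Read a flat YAML or JSON parameter config."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(d: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(dict(d), sort_keys=False))


def law_to_dict(law: LifespanLaw) -> dict:
    return law.to_dict()
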