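"""Fuzzy-set primitives: Gaussian membership functions, fuzzification,
product-t-norm rule firing, and weighted-average defuzzification.

A fuzzy set A over a universe X is the graph {(x, mu_A(x)) | x in X} of its
membership function mu_A: X -> [0, 1]. Here every membership function is
Gaussian,

    mu(x; c, sigma) = exp(-(x - c)^2 / (2 sigma^2)),

parameterized by a center c (where membership is exactly 1) and a spread
sigma > 0. A rule bank holds Takagi–Sugeno-style if-then rules: each rule
selects one membership function per input feature as its antecedent, fires
with the product t-norm of the antecedent degrees, and carries consequent
values f_r plus a center-of-area weight wbar_r.

Two defuzzification modes are provided. ``standard`` is the conventional
firing-strength-weighted average sum_r(w_r f_r) / sum_r(w_r); ``as_printed``
is the literal variant sum_r(wbar_r f_r) / sum_r(w_r) that mixes the
center-of-area weights into the numerator only. The standard mode is the
default: it is the form with sane behavior (a weighted mean that stays inside
[min f, max f] and is invariant to rescaling all firing strengths).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

DefuzzMode = Literal["standard", "as_printed"]


class DegenerateFiringError(ZeroDivisionError):
    """All rules fired with strength zero; the weighted average is undefined."""


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership function with center ``c`` and spread ``sigma``."""

    c: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        return membership(self, x)


def membership(mf: GaussianMF, x: float | np.ndarray) -> float | np.ndarray:
    """Membership degree exp(-0.5 ((x - c) / sigma)^2), in (0, 1]."""
    z = (np.asarray(x, dtype=float) - mf.c) / mf.sigma
    out = np.exp(-0.5 * z * z)
    return float(out) if out.shape == () else out


@dataclass(frozen=True)
class FuzzySet:
    """A labeled fuzzy set: linguistic label plus its membership function."""

    label: str
    mf: GaussianMF


@dataclass
class FuzzificationLayer:
    """Per-input-feature banks of fuzzy sets (the adaptive membership layer)."""

    banks: list[list[FuzzySet]]

    def __post_init__(self) -> None:
        for i, bank in enumerate(self.banks):
            if not bank:
                raise ValueError(f"bank {i} is empty")
            labels = [s.label for s in bank]
            if len(labels) != len(set(labels)):
                raise ValueError(f"bank {i} has duplicate labels")

    @property
    def n_features(self) -> int:
        return len(self.banks)


def fuzzify(layer: FuzzificationLayer, x: Sequence[float]) -> list[list[float]]:
    """Membership degrees per feature: degrees[i][m] = mu_{i,m}(x_i)."""
    if len(x) != layer.n_features:
        raise ValueError(f"input length {len(x)} != number of banks {layer.n_features}")
    return [[float(membership(s.mf, xi)) for s in bank] for bank, xi in zip(layer.banks, x)]


@dataclass
class Rule:
    """One if-then rule: antecedent MF index per feature, consequent, weight."""

    antecedents: tuple[int, ...]
    f: float = 0.0
    wbar: float = 1.0


@dataclass
class RuleBank:
    rules: list[Rule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rule bank needs at least one rule")

    def __len__(self) -> int:
        return len(self.rules)


def firing_strengths(rules: RuleBank, degrees: Sequence[Sequence[float]]) -> np.ndarray:
    """Product-t-norm firing strength of each rule over its antecedent degrees."""
    w = np.empty(len(rules))
    for r, rule in enumerate(rules.rules):
        if len(rule.antecedents) != len(degrees):
            raise ValueError(
                f"rule {r} has {len(rule.antecedents)} antecedents for "
                f"{len(degrees)} features"
            )
        acc = 1.0
        for i, m in enumerate(rule.antecedents):
            acc *= degrees[i][m]
        w[r] = acc
    return w


def defuzzify(
    w: Sequence[float],
    wbar: Sequence[float],
    f: Sequence[float],
    mode: DefuzzMode = "standard",
) -> float:
    """Collapse rule activations into a crisp output.

    ``standard``:   sum_i(w_i f_i) / sum_i(w_i)
    ``as_printed``: sum_i(wbar_i f_i) / sum_i(w_i)
    """
    w = np.asarray(w, dtype=float)
    wbar = np.asarray(wbar, dtype=float)
    f = np.asarray(f, dtype=float)
    if not (w.shape == wbar.shape == f.shape) or w.ndim != 1 or w.size == 0:
        raise ValueError("w, wbar, f must be equal-length non-empty vectors")
    denom = w.sum()
    if denom <= 0.0:
        raise DegenerateFiringError("total firing strength is zero")
    if mode == "standard":
        return float((w * f).sum() / denom)
    if mode == "as_printed":
        return float((wbar * f).sum() / denom)
    raise ValueError(f"unknown defuzzification mode {mode!r}")


# ---------------------------------------------------------------------------
# serialization

def system_to_dict(layer: FuzzificationLayer, rules: RuleBank, mode: DefuzzMode) -> dict:
    return {
        "mode": mode,
        "banks": [
            [{"label": s.label, "c": s.mf.c, "sigma": s.mf.sigma} for s in bank]
            for bank in layer.banks
        ],
        "rules": [
            {"antecedents": list(r.antecedents), "f": r.f, "wbar": r.wbar}
            for r in rules.rules
        ],
    }


def system_from_dict(d: dict) -> tuple[FuzzificationLayer, RuleBank, DefuzzMode]:
    layer = FuzzificationLayer(
        banks=[
            [FuzzySet(s["label"], GaussianMF(s["c"], s["sigma"])) for s in bank]
            for bank in d["banks"]
        ]
    )
    rules = RuleBank(
        rules=[Rule(tuple(r["antecedents"]), r["f"], r["wbar"]) for r in d["rules"]]
    )
    return layer, rules, d["mode"]


def save_system(path: str | Path, layer: FuzzificationLayer, rules: RuleBank,
                mode: DefuzzMode = "standard") -> None:
    Path(path).write_text(json.dumps(system_to_dict(layer, rules, mode)), encoding="utf-8")


def load_system(path: str | Path) -> tuple[FuzzificationLayer, RuleBank, DefuzzMode]:
    return system_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
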