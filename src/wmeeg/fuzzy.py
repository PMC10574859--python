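"""Knowledge-based fuzzy transformer.

Per channel, the z-scored (alpha, beta, gamma) band-power ratios feed a
Mamdani fuzzy inference system whose rule base encodes the working-memory
model: lowered alpha and raised beta/gamma indicate stronger engagement of
the working-memory process, so the crisp output in [0, 1] is the degree to
which a channel's spectrum satisfies that model. Applied to all 10
channels this compresses the 30-component feature vector to 10.

Default layout: each input variable carries Low/Medium/High triangular
terms on the z axis with peaks at -3, 0, +3 (inputs are clamped to
[-3, 3], which turns the outer triangles into saturating shoulders);
the output carries Low/Medium/High triangles on [0, 1] peaking at
0, 0.5, 1. Rules score each antecedent term as supporting (+1), neutral
(0) or opposing (-1) the model — alpha Low, beta High and gamma High
support it — and the consequent is High when the score sum is >= +2,
Low when <= -2, Medium otherwise. Inference uses the product t-norm over
antecedents, the maximum firing strength per consequent term, scaled
(Larsen-style) implication with additive aggregation, and centroid
defuzzification on a fixed 1001-point grid so outputs are reproducible
bit-for-bit. Scaling is used instead of clipping because it preserves
each consequent term's centroid, which makes the crisp output monotone
in every input — the property the rule base is meant to encode; clipped
max-aggregated Mamdani output dips during term transitions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureVector, ZScaler, zscore_apply, zscore_fit

__all__ = [
    "TriangularMF",
    "FuzzyRuleBase",
    "default_rule_base",
    "mf_eval",
    "fuzzy_infer",
    "fuzzy_infer_batch",
    "knowledge_transform",
    "control_surface",
    "FuzzyLogicRegression",
    "fuzzy_logic_regress_fit",
    "fuzzy_logic_regress_predict",
]

Z_LIMIT = 3.0  # inputs clamp to [-Z_LIMIT, Z_LIMIT]
DEFUZZ_GRID = 1001

INPUT_VARS = ("alpha_z", "beta_z", "gamma_z")
TERM_NAMES = ("low", "medium", "high")


@dataclass(frozen=True)
class TriangularMF:
    """Triangle with breakpoints a <= b <= c; membership 1 at b, 0 outside
    [a, c]. Degenerate sides (a == b or b == c) give a vertical edge."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError("breakpoints must satisfy a <= b <= c")

    def __call__(self, x: "float | np.ndarray") -> np.ndarray:
        x = np.asarray(x, dtype=float)
        # degenerate sides (a == b or b == c) are vertical edges
        left = (
            np.where(x >= self.b, 1.0, 0.0)
            if self.b == self.a
            else (x - self.a) / (self.b - self.a)
        )
        right = (
            np.where(x <= self.b, 1.0, 0.0)
            if self.c == self.b
            else (self.c - x) / (self.c - self.b)
        )
        return np.clip(np.minimum(left, right), 0.0, 1.0)


def mf_eval(mf: TriangularMF, x: float) -> float:
    return float(mf(x))


@dataclass
class FuzzyRuleBase:
    """Mamdani system: per-input term sets, a complete rule table over all
    term combinations, output terms on [0, 1], t-norm and defuzzifier."""

    input_terms: dict[str, list[TriangularMF]]
    rules: list[tuple[tuple[int, int, int], int]]
    consequent_terms: list[TriangularMF]
    tnorm: str = "product"
    defuzz: str = "centroid"
    grid_points: int = DEFUZZ_GRID
    _cons_curves: np.ndarray = field(init=False, repr=False, default=None)
    _grid: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if self.tnorm not in ("min", "product"):
            raise ValueError("tnorm must be 'min' or 'product'")
        if self.defuzz != "centroid":
            raise ValueError("only centroid defuzzification is supported")
        n_terms = [len(self.input_terms[v]) for v in INPUT_VARS]
        combos = {r[0] for r in self.rules}
        expected = set(itertools.product(*(range(k) for k in n_terms)))
        if combos != expected:
            raise ValueError("rule table must cover every term combination exactly")
        self._grid = np.linspace(0.0, 1.0, self.grid_points)
        self._cons_curves = np.vstack([mf(self._grid) for mf in self.consequent_terms])

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_terms": {
                    v: [[mf.a, mf.b, mf.c] for mf in terms]
                    for v, terms in self.input_terms.items()
                },
                "rules": [[list(a), c] for a, c in self.rules],
                "consequent_terms": [[mf.a, mf.b, mf.c] for mf in self.consequent_terms],
                "tnorm": self.tnorm,
                "defuzz": self.defuzz,
                "grid_points": self.grid_points,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FuzzyRuleBase":
        d = json.loads(text)
        return cls(
            input_terms={
                v: [TriangularMF(*abc) for abc in terms]
                for v, terms in d["input_terms"].items()
            },
            rules=[(tuple(a), c) for a, c in d["rules"]],
            consequent_terms=[TriangularMF(*abc) for abc in d["consequent_terms"]],
            tnorm=d["tnorm"],
            defuzz=d["defuzz"],
            grid_points=d["grid_points"],
        )


#: antecedent-term score toward the working-memory model, per input.
#: alpha opposes the model when high; beta and gamma support it when high.
_TERM_SCORE = {
    "alpha_z": (+1, 0, -1),  # low, medium, high
    "beta_z": (-1, 0, +1),
    "gamma_z": (-1, 0, +1),
}


def default_rule_base() -> FuzzyRuleBase:
    """The declared default: 3 terms per input, 27 rules scored by how many
    antecedents support the working-memory model."""
    input_terms = {
        v: [
            TriangularMF(-Z_LIMIT, -Z_LIMIT, 0.0),
            TriangularMF(-Z_LIMIT, 0.0, Z_LIMIT),
            TriangularMF(0.0, Z_LIMIT, Z_LIMIT),
        ]
        for v in INPUT_VARS
    }
    consequent_terms = [
        TriangularMF(0.0, 0.0, 0.5),
        TriangularMF(0.0, 0.5, 1.0),
        TriangularMF(0.5, 1.0, 1.0),
    ]
    rules = []
    for combo in itertools.product(range(3), repeat=3):
        score = sum(_TERM_SCORE[v][combo[i]] for i, v in enumerate(INPUT_VARS))
        cons = 2 if score >= 2 else (0 if score <= -2 else 1)
        rules.append((combo, cons))
    return FuzzyRuleBase(input_terms, rules, consequent_terms)


def fuzzy_infer_batch(rb: FuzzyRuleBase, Z: np.ndarray) -> np.ndarray:
    """Vectorised Mamdani evaluation of an (n, 3) array of
    (alpha_z, beta_z, gamma_z) rows -> n crisp outputs in [0, 1]."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != 3:
        raise ValueError("expected (n, 3) inputs (alpha_z, beta_z, gamma_z)")
    Zc = np.clip(Z, -Z_LIMIT, Z_LIMIT)

    # membership degrees per variable: (n, n_terms)
    memberships = [
        np.column_stack([mf(Zc[:, i]) for mf in rb.input_terms[v]])
        for i, v in enumerate(INPUT_VARS)
    ]
    n = Z.shape[0]
    n_cons = len(rb.consequent_terms)
    # aggregate firing strength per consequent term (max over rules)
    strength = np.zeros((n, n_cons))
    for (ia, ib, ig), cons in rb.rules:
        d = (
            memberships[0][:, ia] * memberships[1][:, ib] * memberships[2][:, ig]
            if rb.tnorm == "product"
            else np.minimum(
                np.minimum(memberships[0][:, ia], memberships[1][:, ib]),
                memberships[2][:, ig],
            )
        )
        np.maximum(strength[:, cons], d, out=strength[:, cons])

    out = np.empty(n)
    grid = rb._grid
    curves = rb._cons_curves  # (n_cons, grid)
    chunk = 4096
    for s in range(0, n, chunk):
        st = strength[s : s + chunk]  # (m, n_cons)
        mu = st @ curves  # scaled implication, additive aggregation: (m, grid)
        area = mu.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cent = (mu * grid).sum(axis=1) / area
        # no rule fires (cannot happen with a complete rule table, but be safe)
        cent[area == 0] = 0.5
        out[s : s + chunk] = cent
    return out


def fuzzy_infer(
    rb: FuzzyRuleBase, alpha_z: float, beta_z: float, gamma_z: float
) -> float:
    """Crisp working-memory-model satisfaction degree for one channel."""
    return float(fuzzy_infer_batch(rb, np.array([[alpha_z, beta_z, gamma_z]]))[0])


def knowledge_transform(
    fv: "FeatureVector | np.ndarray",
    scaler: ZScaler,
    rb: FuzzyRuleBase | None = None,
) -> "FeatureVector | np.ndarray":
    """30 -> 10: z-score the raw ratios with the training-set scaler, then
    run each channel's (alpha, beta, gamma) triple through the rule base.

    Accepts a FeatureVector (returns one) or a raw (n, 30) array
    (returns (n, 10)).
    """
    rb = rb or default_rule_base()
    if isinstance(fv, FeatureVector):
        z = zscore_apply(scaler, fv.values[None, :])
        degrees = fuzzy_infer_batch(rb, z.reshape(-1, 3))
        return FeatureVector(
            subject_id=fv.subject_id,
            trial_id=fv.trial_id,
            state=fv.state,
            values=degrees,
            channel_names=fv.channel_names,
            band_names=("wm_degree",),
        )
    X = np.atleast_2d(np.asarray(fv, dtype=float))
    if X.shape[1] != scaler.mu.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} != scaler dimension {scaler.mu.size}"
        )
    if X.shape[1] % 3:
        raise ValueError("feature dimension must be a multiple of 3 (bands per channel)")
    z = zscore_apply(scaler, X)
    n, d = X.shape
    return fuzzy_infer_batch(rb, z.reshape(-1, 3)).reshape(n, d // 3)


def control_surface(
    rb: FuzzyRuleBase,
    grid: int = 21,
    fixed_gamma: float = 0.0,
    z_range: tuple[float, float] = (-Z_LIMIT, Z_LIMIT),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Output over an (alpha_z, beta_z) grid at fixed gamma_z; entry (i, j)
    is the inference at (alpha_i, beta_j). Returns (alphas, betas, surface)."""
    if grid < 2:
        raise ValueError("grid resolution must be >= 2")
    alphas = np.linspace(*z_range, grid)
    betas = np.linspace(*z_range, grid)
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    Z = np.column_stack([A.ravel(), B.ravel(), np.full(A.size, fixed_gamma)])
    surface = fuzzy_infer_batch(rb, Z).reshape(grid, grid)
    return alphas, betas, surface


@dataclass
class FuzzyLogicRegression:
    """The fuzzy part used alone as a predictor: an affine map on the mean
    per-channel model-satisfaction degree."""

    scaler: ZScaler
    rb: FuzzyRuleBase
    slope: float
    intercept: float


def fuzzy_logic_regress_fit(
    F: np.ndarray, y: np.ndarray, rb: FuzzyRuleBase | None = None
) -> FuzzyLogicRegression:
    """Least-squares fit of y on the mean transformed degree; degenerates
    gracefully to a constant when the transform output has no variance."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    y = np.asarray(y, dtype=float)
    if F.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    rb = rb or default_rule_base()
    scaler = zscore_fit(F)
    g = knowledge_transform(F, scaler, rb).mean(axis=1)
    if np.ptp(g) < 1e-12:
        import warnings

        warnings.warn("transform output constant; fitting intercept only", stacklevel=2)
        return FuzzyLogicRegression(scaler, rb, 0.0, float(y.mean()))
    slope, intercept = np.polyfit(g, y, 1)
    return FuzzyLogicRegression(scaler, rb, float(slope), float(intercept))


def fuzzy_logic_regress_predict(model: FuzzyLogicRegression, X: np.ndarray) -> np.ndarray:
    g = knowledge_transform(np.atleast_2d(X), model.scaler, model.rb).mean(axis=1)
    return model.slope * g + model.intercept
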