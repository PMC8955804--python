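"""Patch-grid construction and concentration -> CMYK estimators.

The calibration cross-product: ``n_mel x n_hem`` pigment-concentration levels
(30 x 30 = 900 by default), each patch carrying the per-pigment RGB encodings
of its concentrations and the CMYK targets for the melanin and hemoglobin
print layers. Three interchangeable estimators map the 6-vector of RGB
encodings to the 8-vector of layer CMYK values:

* a nearest-neighbour lookup table (RMS feature distance),
* per-channel ordinary least squares on log-RGB features,
* a small fully connected network (hidden layers 20/30/20, ReLU, Adam).

Leave-one-out cross-validation and a paired t-test compare them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neural_network import MLPRegressor

from .synth import VirtualPress, virtual_print_capture
from .types import EPSILON, PigmentBasis

LOG_FLOOR = EPSILON  # guard for log features


def make_levels(n: int, c_min: float = 0.0, c_max: float = 1.0) -> np.ndarray:
    """``n`` equally spaced concentration levels, endpoints included."""
    if n < 2:
        raise ValueError(f"need at least 2 levels, got {n}")
    if not c_min < c_max:
        raise ValueError(f"c_min ({c_min}) must be < c_max ({c_max})")
    return np.linspace(c_min, c_max, n)


def pigment_color(c, vector: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """RGB encoding of a pigment concentration: ``exp(-(c*vector + bias))``.

    ``c`` may be a scalar or an array; output gains a trailing RGB axis and is
    clamped to ``[EPSILON, 1]``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    density = c[..., None] * np.asarray(vector, float) + np.asarray(bias, float)
    return np.clip(np.exp(-density), EPSILON, 1.0)


def ucr_transform(rgb: np.ndarray) -> np.ndarray:
    """Naive under-colour-removal RGB -> CMYK (the default ColorTransform).

    ``K = 1 - max(R,G,B)``; the chromatic inks are the residual absorptions
    renormalised by ``1 - K``. Pure black maps to ``(0,0,0,1)``.
    """
    rgb = np.asarray(rgb, dtype=float)
    k = 1.0 - rgb.max(axis=-1)
    denom = np.where(k < 1.0, 1.0 - k, 1.0)
    cmy = (1.0 - rgb - k[..., None]) / denom[..., None]
    cmy = np.where(k[..., None] < 1.0, cmy, 0.0)
    return np.clip(np.concatenate([cmy, k[..., None]], axis=-1), 0.0, 1.0)


def rgb_to_cmyk(rgb: np.ndarray, transform=None) -> np.ndarray:
    """Apply a ColorTransform (default: ``ucr_transform``) to in-range RGB."""
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError("rgb components must lie in [0, 1]")
    return (transform or ucr_transform)(rgb)


@dataclass
class PatchSpec:
    """One calibration patch: levels, concentrations, encodings, targets."""

    mel_level_index: int
    hem_level_index: int
    mel_concentration: float
    hem_concentration: float
    mel_rgb: np.ndarray
    hem_rgb: np.ndarray
    mel_cmyk: np.ndarray
    hem_cmyk: np.ndarray


@dataclass
class PatchSet:
    """The full calibration grid, stored column-wise for vector maths.

    ``patch(i)`` materialises a single :class:`PatchSpec`. ``features()``
    returns the per-patch 6-vector (mel RGB then hem RGB); ``targets()`` the
    8-vector of layer CMYK values.
    """

    mel_idx: np.ndarray
    hem_idx: np.ndarray
    mel_conc: np.ndarray
    hem_conc: np.ndarray
    mel_rgb: np.ndarray
    hem_rgb: np.ndarray
    mel_cmyk: np.ndarray
    hem_cmyk: np.ndarray
    n_mel: int
    n_hem: int
    basis: PigmentBasis | None = None

    def __post_init__(self) -> None:
        n = len(self.mel_idx)
        if n != self.n_mel * self.n_hem:
            raise ValueError(
                f"{n} patches but grid is {self.n_mel} x {self.n_hem}"
            )
        pairs = set(zip(self.mel_idx.tolist(), self.hem_idx.tolist()))
        if len(pairs) != n:
            raise ValueError("duplicate (mel, hem) level index pairs")

    def __len__(self) -> int:
        return len(self.mel_idx)

    def patch(self, i: int) -> PatchSpec:
        return PatchSpec(
            mel_level_index=int(self.mel_idx[i]),
            hem_level_index=int(self.hem_idx[i]),
            mel_concentration=float(self.mel_conc[i]),
            hem_concentration=float(self.hem_conc[i]),
            mel_rgb=self.mel_rgb[i],
            hem_rgb=self.hem_rgb[i],
            mel_cmyk=self.mel_cmyk[i],
            hem_cmyk=self.hem_cmyk[i],
        )

    def features(self) -> np.ndarray:
        return np.concatenate([self.mel_rgb, self.hem_rgb], axis=1)

    def targets(self) -> np.ndarray:
        return np.concatenate([self.mel_cmyk, self.hem_cmyk], axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = {"mel_idx": self.mel_idx, "hem_idx": self.hem_idx,
                "mel_conc": self.mel_conc, "hem_conc": self.hem_conc}
        for tag, arr, names in (
            ("mel_rgb", self.mel_rgb, "RGB"),
            ("hem_rgb", self.hem_rgb, "RGB"),
            ("mel_cmyk", self.mel_cmyk, "CMYK"),
            ("hem_cmyk", self.hem_cmyk, "CMYK"),
        ):
            for j, ch in enumerate(names):
                cols[f"{tag}_{ch}"] = arr[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_mel: int | None = None,
                 n_hem: int | None = None) -> "PatchSet":
        df = pd.read_csv(path)
        n_mel = n_mel or int(df["mel_idx"].max()) + 1
        n_hem = n_hem or int(df["hem_idx"].max()) + 1
        get = lambda tag, names: df[[f"{tag}_{c}" for c in names]].to_numpy()
        return cls(
            mel_idx=df["mel_idx"].to_numpy(),
            hem_idx=df["hem_idx"].to_numpy(),
            mel_conc=df["mel_conc"].to_numpy(),
            hem_conc=df["hem_conc"].to_numpy(),
            mel_rgb=get("mel_rgb", "RGB"),
            hem_rgb=get("hem_rgb", "RGB"),
            mel_cmyk=get("mel_cmyk", "CMYK"),
            hem_cmyk=get("hem_cmyk", "CMYK"),
            n_mel=n_mel,
            n_hem=n_hem,
        )


def build_patch_set(
    n_mel: int,
    n_hem: int,
    basis: PigmentBasis,
    mel_range: tuple[float, float] = (0.0, 1.0),
    hem_range: tuple[float, float] = (0.0, 1.0),
    transform=None,
) -> PatchSet:
    """Build the nominal calibration grid (``n_mel * n_hem`` patches).

    Each patch's RGB encodings are deterministic functions of its
    concentrations given the basis; CMYK targets come from the colour
    transform applied to those encodings.
    """
    def levels(n: int, rng: tuple[float, float]) -> np.ndarray:
        if n == 1:  # degenerate grid: single level at the range midpoint
            return np.array([0.5 * (rng[0] + rng[1])])
        return make_levels(n, *rng)

    mel_levels = levels(n_mel, mel_range)
    hem_levels = levels(n_hem, hem_range)
    mi, hi = np.meshgrid(np.arange(n_mel), np.arange(n_hem), indexing="ij")
    mi, hi = mi.ravel(), hi.ravel()
    mel_c = mel_levels[mi]
    hem_c = hem_levels[hi]
    mel_rgb = pigment_color(mel_c, basis.melanin_vector, basis.bias)
    hem_rgb = pigment_color(hem_c, basis.hemoglobin_vector, basis.bias)
    return PatchSet(
        mel_idx=mi,
        hem_idx=hi,
        mel_conc=mel_c,
        hem_conc=hem_c,
        mel_rgb=mel_rgb,
        hem_rgb=hem_rgb,
        mel_cmyk=rgb_to_cmyk(mel_rgb, transform),
        hem_cmyk=rgb_to_cmyk(hem_rgb, transform),
        n_mel=n_mel,
        n_hem=n_hem,
        basis=basis,
    )


def measure_patch_set(
    ps: PatchSet,
    press: VirtualPress | None = None,
    basis: PigmentBasis | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> PatchSet:
    """Run the hardware-free print-and-capture loop over a patch set.

    Each patch's CMYK targets are "printed" through the virtual press,
    "photographed" (optional sensor noise) and the observed density is
    decomposed against the pigment basis by least squares, giving *measured*
    concentrations and RGB encodings. Targets are unchanged — calibration then
    learns measured appearance -> printed CMYK, mirroring a photographed patch
    chart.

    The measured per-pigment RGB encoding is the observed colour *attributed*
    to that layer: the total density minus the other layer's nominal
    contribution and the baseline. Measurement cross-talk — the other layer's
    deviation from nominal and the press density component outside the
    two-pigment span — therefore stays in the encodings, which is exactly the
    redundancy that makes the three log-RGB channels per layer informative
    rather than collinear.
    """
    press = press or VirtualPress()
    basis = basis or ps.basis
    if basis is None:
        raise ValueError("a pigment basis is required to measure patches")
    rgb = virtual_print_capture(ps.mel_cmyk, ps.hem_cmyk, press)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        rgb = np.clip(rgb + rng.normal(0, noise_sigma, rgb.shape), EPSILON, 1.0)
    density = -np.log(rgb)
    a = np.column_stack([basis.melanin_vector, basis.hemoglobin_vector])
    conc, *_ = np.linalg.lstsq(a, (density - basis.bias).T, rcond=None)
    mel_c = np.clip(conc[0], 0.0, None)
    hem_c = np.clip(conc[1], 0.0, None)
    mel_density = density - np.outer(ps.hem_conc, basis.hemoglobin_vector) - basis.bias
    hem_density = density - np.outer(ps.mel_conc, basis.melanin_vector) - basis.bias
    return replace(
        ps,
        mel_conc=mel_c,
        hem_conc=hem_c,
        mel_rgb=np.clip(np.exp(-mel_density), EPSILON, 1.0),
        hem_rgb=np.clip(np.exp(-hem_density), EPSILON, 1.0),
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


@dataclass
class LUTEstimator:
    """Nearest stored patch by RMS distance in the 6-vector feature space.

    Exact-hit queries return the stored CMYK with zero error; ties go to the
    lowest patch index.
    """

    features_: np.ndarray
    targets_: np.ndarray

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        out = np.empty((features.shape[0], self.targets_.shape[1]))
        # chunked exhaustive scan; argmin returns the lowest index on ties
        step = max(1, 2_000_000 // max(len(self.features_), 1))
        for lo in range(0, features.shape[0], step):
            d2 = (
                (features[lo : lo + step, None, :] - self.features_[None]) ** 2
            ).mean(axis=2)
            out[lo : lo + step] = self.targets_[np.argmin(d2, axis=1)]
        return out


def fit_lut(ps: PatchSet) -> LUTEstimator:
    if len(ps) == 0:
        raise ValueError("cannot build a LUT from an empty patch set")
    return LUTEstimator(features_=ps.features().copy(), targets_=ps.targets().copy())


def _log_features(rgb: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(rgb, LOG_FLOOR))


@dataclass
class RegressionModel:
    """Per-channel OLS on log-RGB features, one coefficient set per layer.

    ``coef_mel``/``coef_hem`` have shape (4 outputs, 4 params): ``a_R, a_G,
    a_B, b`` per CMYK channel. Predictions are clamped to [0, 1].
    """

    coef_mel: np.ndarray
    coef_hem: np.ndarray
    clip: bool = True

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        xm = np.column_stack(
            [_log_features(features[:, :3]), np.ones(len(features))]
        )
        xh = np.column_stack(
            [_log_features(features[:, 3:]), np.ones(len(features))]
        )
        pred = np.concatenate([xm @ self.coef_mel.T, xh @ self.coef_hem.T], axis=1)
        return np.clip(pred, 0.0, 1.0) if self.clip else pred


def fit_regression(ps: PatchSet, cond_limit: float = 1e10) -> RegressionModel:
    """Fit the log-linear regression ``D_i = a_R log R + a_G log G + a_B log B + b``.

    One OLS per output channel and layer. Rejects rank-deficient designs —
    note the nominal grid *is* rank-deficient (each pigment's three log
    channels are all linear in its 1-D concentration sweep); fit on measured
    patches (:func:`measure_patch_set`).
    """
    if len(ps) < 4:
        raise ValueError("regression needs at least 4 patches")
    coefs = []
    for rgb, cmyk, layer in (
        (ps.mel_rgb, ps.mel_cmyk, "melanin"),
        (ps.hem_rgb, ps.hem_cmyk, "hemoglobin"),
    ):
        x = np.column_stack([_log_features(rgb), np.ones(len(ps))])
        s = np.linalg.svd(x, compute_uv=False)
        cond = s[0] / s[-1] if s[-1] > 0 else np.inf
        if cond > cond_limit:
            raise ValueError(
                f"{layer}-layer log-RGB design is rank-deficient "
                f"(condition number {cond:.3e}, singular values {s})"
            )
        beta, *_ = np.linalg.lstsq(x, cmyk, rcond=None)
        coefs.append(beta.T)
    return RegressionModel(coef_mel=coefs[0], coef_hem=coefs[1])


def plant_linear_targets(
    ps: PatchSet, coef_mel: np.ndarray, coef_hem: np.ndarray
) -> PatchSet:
    """Replace CMYK targets with exact values from the log-linear model class.

    Used for parameter-recovery experiments; raises if any planted target
    leaves [0, 1] (which would break the estimators' output contract).
    """
    model = RegressionModel(
        coef_mel=np.asarray(coef_mel, float),
        coef_hem=np.asarray(coef_hem, float),
        clip=False,
    )
    pred = model.predict(ps.features())
    if np.any(pred < 0) or np.any(pred > 1):
        raise ValueError("planted coefficients push CMYK outside [0, 1]")
    return replace(ps, mel_cmyk=pred[:, :4], hem_cmyk=pred[:, 4:])


@dataclass
class MLPModel:
    """Two small fully connected networks (one per colored layer).

    Architecture: 3 inputs -> 20 -> 30 -> 20 hidden (ReLU) -> 4 outputs,
    trained with Adam on mean-squared error. Inputs are standardised with
    training statistics. Predictions are clamped to [0, 1].
    """

    net_mel: MLPRegressor
    net_hem: MLPRegressor
    scale_mel: tuple[np.ndarray, np.ndarray]
    scale_hem: tuple[np.ndarray, np.ndarray]
    epochs: int
    seed: int

    @staticmethod
    def _count(net: MLPRegressor) -> int:
        return sum(c.size for c in net.coefs_) + sum(b.size for b in net.intercepts_)

    def n_parameters(self) -> tuple[int, int]:
        """Trainable parameter count of each network."""
        return self._count(self.net_mel), self._count(self.net_hem)

    def loss_curves(self) -> tuple[list[float], list[float]]:
        return list(self.net_mel.loss_curve_), list(self.net_hem.loss_curve_)

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        out = []
        for net, (mu, sd), sl in (
            (self.net_mel, self.scale_mel, slice(0, 3)),
            (self.net_hem, self.scale_hem, slice(3, 6)),
        ):
            out.append(net.predict((features[:, sl] - mu) / sd))
        return np.clip(np.concatenate(out, axis=1), 0.0, 1.0)


def fit_mlp(ps: PatchSet, epochs: int = 30, seed: int = 0) -> MLPModel:
    """Train the two-network CMYK estimator, seed-deterministically."""
    if len(ps) == 0:
        raise ValueError("cannot train on an empty patch set")

    def train(x: np.ndarray, y: np.ndarray, net_seed: int):
        mu, sd = x.mean(axis=0), x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        net = MLPRegressor(
            hidden_layer_sizes=(20, 30, 20),
            activation="relu",
            solver="adam",
            learning_rate_init=1e-3,
            batch_size=min(32, len(x)),
            max_iter=epochs,
            shuffle=True,
            random_state=net_seed,
            tol=0.0,
            n_iter_no_change=max(epochs, 10),
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # ConvergenceWarning: epoch budget is fixed
            net.fit(x_scaled := (x - mu) / sd, y)
        if not np.isfinite(net.loss_):
            raise RuntimeError(f"MLP training diverged (loss {net.loss_})")
        return net, (mu, sd)

    net_m, scale_m = train(ps.mel_rgb, ps.mel_cmyk, seed)
    net_h, scale_h = train(ps.hem_rgb, ps.hem_cmyk, seed + 1)
    return MLPModel(
        net_mel=net_m,
        net_hem=net_h,
        scale_mel=scale_m,
        scale_hem=scale_h,
        epochs=epochs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

_FITTERS = {
    "lut": lambda ps, seed, epochs: fit_lut(ps),
    "regression": lambda ps, seed, epochs: fit_regression(ps),
    "mlp": lambda ps, seed, epochs: fit_mlp(ps, epochs=epochs, seed=seed),
}


def _subset(ps: PatchSet, keep: np.ndarray) -> PatchSet:
    sub = PatchSet.__new__(PatchSet)
    for name in ("mel_idx", "hem_idx", "mel_conc", "hem_conc",
                 "mel_rgb", "hem_rgb", "mel_cmyk", "hem_cmyk"):
        setattr(sub, name, getattr(ps, name)[keep])
    sub.n_mel = len(sub.mel_idx)  # degrade grid bookkeeping for folds
    sub.n_hem = 1
    sub.basis = ps.basis
    return sub


def loocv(
    ps: PatchSet, method: str, seed: int = 0, epochs: int = 30
) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validation of an estimator over the patch set.

    For every patch the estimator is fitted on the remaining patches and
    predicts the held-out 8-vector (two CMYK quadruples). Returns the overall
    RMSE (over all held-out components) and the per-patch RMS errors.
    """
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; valid: {sorted(_FITTERS)}")
    n = len(ps)
    if n < 2:
        raise ValueError("LOOCV needs at least 2 patches")
    feats, targets = ps.features(), ps.targets()
    if method == "lut":
        # train-on-rest nearest neighbour == full scan with self excluded
        d2 = ((feats[:, None, :] - feats[None]) ** 2).mean(axis=2)
        np.fill_diagonal(d2, np.inf)
        pred = targets[np.argmin(d2, axis=1)]
    else:
        pred = np.empty_like(targets)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            model = _FITTERS[method](_subset(ps, keep), seed, epochs)
            pred[i] = model.predict(feats[i : i + 1])[0]
    sq = (pred - targets) ** 2
    return float(np.sqrt(sq.mean())), np.sqrt(sq.mean(axis=1))


@dataclass
class MethodComparison:
    p_value: float
    significant: bool
    degenerate: bool = False


def compare_methods(
    errors_a: np.ndarray, errors_b: np.ndarray, alpha: float = 0.05
) -> MethodComparison:
    """Two-sided paired t-test on matched per-patch LOOCV errors."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"error vectors differ in length: {a.shape} vs {b.shape}")
    diff = a - b
    if np.all(diff == diff[0]):  # identical differences: t is undefined
        return MethodComparison(p_value=1.0, significant=False, degenerate=True)
    t = stats.ttest_rel(a, b)
    p = float(t.pvalue)
    return MethodComparison(p_value=p, significant=bool(p < alpha))
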