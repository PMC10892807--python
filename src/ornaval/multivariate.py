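"""Principal component screening and PLS path modelling.

PCA is an eigen-decomposition of the correlation matrix of the indicator
data, implemented directly (the decomposition, ordering and sign conventions
are part of this package's contract and are cross-checked against an SVD
oracle in the test suite). The structural model mirrors the study's design:
a binary warming indicator feeds latent trait blocks (each proxied by the
first principal component of its indicators), which feed the comprehensive
ornamental score. The PLS path-modelling engine implements the classic
iterative outer/inner approximation (Lohmoller/Wold); with single-indicator
blocks it reduces exactly to standardized least-squares path analysis, which
the tests exploit as an oracle. Edge uncertainty comes from a case-resampling
bootstrap with percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PcaResult",
    "BlockSpec",
    "PathModel",
    "PathResult",
    "standardize",
    "pca",
    "block_scores",
    "fit_pls_sem",
    "bootstrap_paths",
    "default_path_model",
]

PLS_TOL = 1e-7
PLS_MAX_ITER = 300
#: standardized coefficients beyond this indicate a numerically singular
#: predecessor set and raise instead of being reported
COEF_CAP = 1e3


def standardize(data: pd.DataFrame | np.ndarray, ddof: int = 1):
    """Columns to mean 0, SD 1 (denominator n - ddof); errors on constants."""
    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float)
        cols = list(data.columns)
    else:
        arr = np.asarray(data, dtype=float)
        cols = [str(i) for i in range(arr.shape[1])]
    if np.isnan(arr).any():
        raise ValueError("standardize requires complete data (drop missing rows first)")
    sd = arr.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        raise ValueError(f"zero-variance column(s): {', '.join(cols[i] for i in zero)}")
    z = (arr - arr.mean(axis=0)) / sd
    if isinstance(data, pd.DataFrame):
        return pd.DataFrame(z, index=data.index, columns=data.columns)
    return z


@dataclass
class PcaResult:
    """Correlation-matrix PCA: loadings, scores, eigenvalues, variance shares."""

    loadings: pd.DataFrame  # indicators x components, orthonormal columns
    scores: pd.DataFrame  # observations x components
    eigenvalues: np.ndarray  # non-increasing
    variance_fraction: np.ndarray  # percent, sums to 100
    cumulative_variance: np.ndarray  # percent

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca(data: pd.DataFrame) -> PcaResult:
    """PCA on the correlation matrix of complete-case rows.

    Components are ordered by eigenvalue; each loading column's sign is fixed
    so its largest-magnitude entry is positive; scores are the standardized
    data projected on the loadings.
    """
    data = data.dropna()
    if len(data) < 2:
        raise ValueError("PCA needs at least 2 complete observations")
    if data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 indicators")
    z = standardize(data)
    zz = z.to_numpy()
    corr = zz.T @ zz / (len(zz) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comp = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=data.columns, columns=comp)
    scores = pd.DataFrame(zz @ eigvec, index=data.index, columns=comp)
    frac = 100.0 * eigval / eigval.sum()
    return PcaResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigval,
        variance_fraction=frac,
        cumulative_variance=np.cumsum(frac),
    )


@dataclass(frozen=True)
class BlockSpec:
    """A latent block: name plus the indicator columns that measure it."""

    name: str
    indicators: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.indicators:
            raise ValueError(f"block {self.name!r} has no indicators")


def block_scores(
    data: pd.DataFrame, blocks: Sequence[BlockSpec]
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """First-PC proxy score per block, standardized, plus indicator signs.

    Each block's PCA runs on its own indicators only (complete cases across
    all block indicators). The sign map reports each indicator's correlation
    with its block proxy (the up/down annotation of the structural diagram).
    """
    all_cols = [c for b in blocks for c in b.indicators]
    sub = data[all_cols].dropna()
    if sub.empty:
        raise ValueError("no complete observations across block indicators")
    scores = {}
    signs: dict[str, dict[str, float]] = {}
    for b in blocks:
        cols = list(b.indicators)
        if sub[cols].isna().all().any():
            raise ValueError(f"block {b.name!r} has an all-missing indicator")
        if len(cols) == 1:
            proxy = standardize(sub[cols]).iloc[:, 0].to_numpy()
        else:
            proxy = pca(sub[cols]).scores["PC1"].to_numpy()
            proxy = (proxy - proxy.mean()) / proxy.std(ddof=1)
        scores[b.name] = proxy
        z = standardize(sub[cols]).to_numpy()
        signs[b.name] = {
            c: float(z[:, k] @ proxy / (len(proxy) - 1)) for k, c in enumerate(cols)
        }
    return pd.DataFrame(scores, index=sub.index), signs


@dataclass
class PathModel:
    """Latent blocks plus an acyclic inner path structure.

    ``blocks`` maps each latent to its indicator columns; ``edges`` are
    directed (source, target) pairs among latents. The weighting scheme for
    the inner approximation is 'path' (default), 'factorial' or 'centroid'.
    """

    blocks: dict[str, tuple[str, ...]]
    edges: list[tuple[str, str]]
    scheme: str = "path"

    def __post_init__(self) -> None:
        if self.scheme not in ("path", "factorial", "centroid"):
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")
        names = set(self.blocks)
        for s, t in self.edges:
            if s not in names or t not in names:
                raise ValueError(f"edge ({s}, {t}) references unknown latent")
            if s == t:
                raise ValueError("self-loops are not allowed")
        self.topological_order()  # raises on cycles

    @property
    def latents(self) -> list[str]:
        return list(self.blocks)

    def predecessors(self, latent: str) -> list[str]:
        return [s for s, t in self.edges if t == latent]

    def successors(self, latent: str) -> list[str]:
        return [t for s, t in self.edges if s == latent]

    def endogenous(self) -> list[str]:
        return [l for l in self.latents if self.predecessors(l)]

    def topological_order(self) -> list[str]:
        indeg = {l: len(self.predecessors(l)) for l in self.latents}
        queue = [l for l in self.latents if indeg[l] == 0]
        order: list[str] = []
        while queue:
            l = queue.pop(0)
            order.append(l)
            for t in self.successors(l):
                indeg[t] -= 1
                if indeg[t] == 0:
                    queue.append(t)
        if len(order) != len(self.latents):
            raise ValueError("inner path structure must be acyclic")
        return order

    def to_dict(self) -> dict:
        return {
            "blocks": {k: list(v) for k, v in self.blocks.items()},
            "edges": [list(e) for e in self.edges],
            "scheme": self.scheme,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathModel":
        return cls(
            blocks={k: tuple(v) for k, v in d["blocks"].items()},
            edges=[tuple(e) for e in d["edges"]],
            scheme=d.get("scheme", "path"),
        )


@dataclass
class PathResult:
    """Estimated PLS path model."""

    path_coefficients: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    latent_scores: pd.DataFrame
    outer_weights: dict[str, dict[str, float]]
    iterations: int
    bootstrap: pd.DataFrame | None = None  # per-edge mean, se, ci_low, ci_high, significant

    def coefficient(self, source: str, target: str) -> float:
        return self.path_coefficients[(source, target)]


class PLSConvergenceError(RuntimeError):
    pass


def _pls_weights(
    X: dict[str, np.ndarray], model: PathModel
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], int]:
    """Iterative outer/inner approximation; returns weights, scores, iterations.

    Outer mode A (correlation weights); latent scores scaled to unit variance
    (ddof=1); sign fixed so each block's summed indicator correlation is
    non-negative. Single-indicator blocks have weight +1 by construction.
    """
    n = next(iter(X.values())).shape[0]
    latents = model.latents
    w = {l: np.full(X[l].shape[1], 1.0 / np.sqrt(X[l].shape[1])) for l in latents}

    def score(l: str, wl: np.ndarray) -> np.ndarray:
        y = X[l] @ wl
        sd = y.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"degenerate latent score for block {l!r}")
        return y / sd

    Y = {l: score(l, w[l]) for l in latents}
    multi = any(X[l].shape[1] > 1 for l in latents)
    if not multi:
        # all blocks single-indicator: weights are fixed at +1
        w = {l: np.array([1.0]) for l in latents}
        Y = {l: score(l, w[l]) for l in latents}
        return w, Y, 1

    corr = lambda a, b: float(a @ b) / (n - 1)
    for it in range(1, PLS_MAX_ITER + 1):
        # inner approximation
        Z: dict[str, np.ndarray] = {}
        for l in latents:
            acc = np.zeros(n)
            preds = model.predecessors(l)
            succs = model.successors(l)
            if model.scheme == "path" and preds:
                P = np.column_stack([Y[p] for p in preds])
                beta, *_ = np.linalg.lstsq(P, Y[l], rcond=None)
                acc += P @ beta
            else:
                for p in preds:
                    e = corr(Y[p], Y[l])
                    acc += (np.sign(e) if model.scheme == "centroid" else e) * Y[p]
            for s in succs:
                e = corr(Y[s], Y[l])
                acc += (np.sign(e) if model.scheme == "centroid" else e) * Y[s]
            if not preds and not succs:
                acc = Y[l].copy()  # isolated latent keeps its own proxy
            Z[l] = acc
        # outer update (mode A)
        w_new: dict[str, np.ndarray] = {}
        delta = 0.0
        for l in latents:
            wl = X[l].T @ Z[l] / (n - 1)
            y = X[l] @ wl
            sd = y.std(ddof=1)
            if sd <= 0:
                raise ValueError(f"degenerate latent score for block {l!r}")
            wl = wl / sd
            if (X[l].T @ (X[l] @ wl)).sum() < 0:  # sign: summed indicator corr >= 0
                wl = -wl
            w_new[l] = wl
            delta = max(delta, float(np.max(np.abs(wl - w[l]))))
        w = w_new
        Y = {l: score(l, w[l]) for l in latents}
        if delta < PLS_TOL:
            return w, Y, it
    raise PLSConvergenceError(
        f"PLS weights did not converge in {PLS_MAX_ITER} iterations "
        f"(last max weight change {delta:.3e})"
    )


def fit_pls_sem(indicator_data: pd.DataFrame, model: PathModel) -> PathResult:
    """Estimate the structural model on complete-case indicator data.

    After the outer/inner iteration converges (max absolute weight change
    below 1e-7), each endogenous latent is regressed by ordinary least
    squares on its predecessors' scores; because all scores are standardized
    the coefficients are standardized path coefficients, and R-squared is the
    usual coefficient of determination. With single-indicator blocks the
    whole procedure reduces exactly to standardized path analysis.
    """
    cols = [c for b in model.blocks.values() for c in b]
    missing = [c for c in cols if c not in indicator_data.columns]
    if missing:
        raise ValueError(f"indicator columns absent from data: {missing}")
    sub = indicator_data[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete observations")
    Z = standardize(sub)
    X = {l: Z[list(model.blocks[l])].to_numpy() for l in model.latents}
    w, Y, iters = _pls_weights(X, model)
    n = len(sub)
    coefs: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    for l in model.endogenous():
        preds = model.predecessors(l)
        P = np.column_stack([Y[p] for p in preds])
        gram = P.T @ P / (n - 1)
        if np.linalg.cond(gram) > 1e10:
            raise ValueError(f"singular predecessor set for latent {l!r}")
        beta = np.linalg.solve(gram, P.T @ Y[l] / (n - 1))
        if np.any(np.abs(beta) > COEF_CAP):
            raise ValueError(f"path coefficients for {l!r} exceed the numerical cap")
        for p, b in zip(preds, beta):
            coefs[(p, l)] = float(b)
        resid = Y[l] - P @ beta
        r2[l] = float(1.0 - resid @ resid / (Y[l] @ Y[l]))
    scores = pd.DataFrame({l: Y[l] for l in model.latents}, index=sub.index)
    weights = {
        l: dict(zip(model.blocks[l], w[l].tolist())) for l in model.latents
    }
    return PathResult(
        path_coefficients=coefs,
        r_squared=r2,
        latent_scores=scores,
        outer_weights=weights,
        iterations=iters,
    )


def bootstrap_paths(
    indicator_data: pd.DataFrame,
    model: PathModel,
    replicates: int = 500,
    seed: int | np.random.SeedSequence = 0,
    max_redraws: int | None = None,
) -> pd.DataFrame:
    """Case-resampling bootstrap of the path coefficients.

    Resamples plants with replacement, refits, and reports per-edge mean, SE,
    percentile 95% CI and a significance flag (CI excludes 0). Replicates
    that fail to converge or are degenerate are redrawn, up to ``max_redraws``
    (default 10x replicates). Deterministic under a fixed seed.
    """
    if replicates < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    cols = [c for b in model.blocks.values() for c in b]
    sub = indicator_data[cols].dropna().reset_index(drop=True)
    base = fit_pls_sem(sub, model)
    edges = list(base.path_coefficients)
    rng = np.random.default_rng(seed)
    n = len(sub)
    draws = np.empty((replicates, len(edges)))
    cap = max_redraws if max_redraws is not None else 10 * replicates
    attempts = 0
    done = 0
    while done < replicates:
        if attempts >= replicates + cap:
            raise RuntimeError("too many failed bootstrap replicates")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            fit = fit_pls_sem(sub.iloc[idx], model)
        except (ValueError, PLSConvergenceError):
            continue
        draws[done] = [fit.path_coefficients[e] for e in edges]
        done += 1
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    out = pd.DataFrame(
        {
            "source": [e[0] for e in edges],
            "target": [e[1] for e in edges],
            "estimate": [base.path_coefficients[e] for e in edges],
            "boot_mean": draws.mean(axis=0),
            "boot_se": draws.std(axis=0, ddof=1),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    out["significant"] = (out["ci_low"] > 0) | (out["ci_high"] < 0)
    return out


def default_path_model(
    variant: str = "two-flowering-blocks", score_column: str = "score"
) -> PathModel:
    """Structural model of the study: warming -> trait blocks -> score.

    Variants: 'two-flowering-blocks' splits flowering into floral morphology
    & color vs florescence & flower number (as in the published diagram);
    'one-flowering-block' merges them.
    """
    morphology = ("plant_height", "branch_number", "crown_width", "single_leaf_area")
    floral_morph = (
        "vexillum_length",
        "corolla_diameter",
        "corolla_tube_length",
        "nectar_spur_length",
        "nectar_spur_curvature",
        "stripe_number",
        "pedicel_length",
        "anthocyanin_vexillum",
    )
    florescence = ("flower_longevity", "flowering_duration", "flower_number")
    if variant == "two-flowering-blocks":
        blocks = {
            "warming": ("warming",),
            "plant_morphology": morphology,
            "floral_morphology_color": floral_morph,
            "florescence_flower_number": florescence,
            "ornamental_score": (score_column,),
        }
        edges = [
            ("warming", "plant_morphology"),
            ("warming", "floral_morphology_color"),
            ("warming", "florescence_flower_number"),
            ("plant_morphology", "ornamental_score"),
            ("floral_morphology_color", "ornamental_score"),
            ("florescence_flower_number", "ornamental_score"),
        ]
    elif variant == "one-flowering-block":
        blocks = {
            "warming": ("warming",),
            "plant_morphology": morphology,
            "flowering_traits": floral_morph + florescence,
            "ornamental_score": (score_column,),
        }
        edges = [
            ("warming", "plant_morphology"),
            ("warming", "flowering_traits"),
            ("plant_morphology", "ornamental_score"),
            ("flowering_traits", "ornamental_score"),
        ]
    else:
        raise ValueError(f"unknown model variant {variant!r}")
    return PathModel(blocks=blocks, edges=edges)
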