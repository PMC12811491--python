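"""Dual-regularized partial least squares between two data domains.

Each component is a pair of unit-norm weight vectors (w_c on the
connectivity domain, w_p on the phenotypic domain) maximizing the sample
covariance between the latent scores phi = C w_c and psi = P w_p, subject
to per-domain L1 budgets ||w||_1 <= lambda with lambda in [1, sqrt(|D|)]
(lambda = 1 is maximal regularization, lambda = sqrt(|D|) none — the L1
ball then contains the whole unit L2 sphere).  Sparsity is achieved by
alternating soft-thresholded power updates of the cross-covariance
matrix, and successive components are obtained by projection deflation
of both domains on their own latent scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegularizationSpec",
    "PLSComponent",
    "RPLSResults",
    "TripleNetworkPLS",
    "standardize_domains",
    "cross_covariance",
    "leading_pair",
    "soft_threshold_unit",
    "sparse_pair",
    "deflate",
    "fit_rpls",
    "select_lambda_c",
    "select_lambda_p",
]

MAX_ITER = 500
TOL = 1e-8
N_BISECT = 60


@dataclass(frozen=True)
class RegularizationSpec:
    """Per-domain L1 budgets; valid range is [1, sqrt(n_variables)]."""

    lambda_c: float
    lambda_p: float

    def validate(self, n_c: int, n_p: int) -> None:
        for lam, dim, name in ((self.lambda_c, n_c, "lambda_c"), (self.lambda_p, n_p, "lambda_p")):
            if not (1.0 - 1e-12 <= lam <= np.sqrt(dim) + 1e-12):
                raise ValueError(
                    f"{name}={lam} outside the admissible range [1, sqrt({dim})]"
                )


def standardize_domains(
    C_raw: np.ndarray, P_raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise z-scoring (mean 0, sample sd 1) of both domains."""
    if C_raw.shape[0] != P_raw.shape[0]:
        raise ValueError("domains must have the same number of rows")
    if C_raw.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    out = []
    for name, X in (("connectivity", C_raw), ("phenotype", P_raw)):
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"constant {name} column(s) at index {bad.tolist()}")
        out.append((X - X.mean(axis=0)) / sd)
    return out[0], out[1]


def cross_covariance(C: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Sample cross-covariance M = C^T P / (n-1) of column-centered domains."""
    if C.shape[0] != P.shape[0]:
        raise ValueError("domains must have the same number of rows")
    return C.T @ P / (C.shape[0] - 1)


def _orient(wc: np.ndarray, wp: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve sign indeterminacy: cov >= 0, then largest-|wp| entry positive."""
    if wc @ M @ wp < 0:
        wp = -wp
    j = int(np.argmax(np.abs(wp)))  # lowest index on ties
    if wp[j] < 0:
        wc, wp = -wc, -wp
    return wc, wp


def leading_pair(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unregularized solution: the leading singular-vector pair of M."""
    M = np.asarray(M, dtype=float)
    if not np.any(M):
        raise ValueError("cross-covariance matrix is identically zero")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    wc, wp = U[:, 0], Vt[0, :]
    return _orient(wc, wp, M)


def soft_threshold_unit(v: np.ndarray, lam: float) -> np.ndarray:
    """Soft-threshold and renormalize so that ||w||_2 = 1 and ||w||_1 <= lam.

    The threshold delta >= 0 is the smallest value (binary search, 60
    bisections) at which the L1 norm of the unit-L2 thresholded vector
    falls inside the budget.
    """
    v = np.asarray(v, dtype=float)
    l2 = np.linalg.norm(v)
    if l2 == 0:
        raise ValueError("cannot threshold a zero vector")
    if not (1.0 - 1e-12 <= lam <= np.sqrt(v.size) + 1e-12):
        raise ValueError(f"lambda={lam} outside [1, sqrt({v.size})]")
    if np.linalg.norm(v, 1) / l2 <= lam:
        return v / l2
    a = np.abs(v)
    # prefix sums over the sorted magnitudes give the L1/L2 norms of the
    # thresholded vector in O(log E) per bisection step
    asort = np.sort(a)
    s1 = np.concatenate([[0.0], np.cumsum(asort)])
    s2 = np.concatenate([[0.0], np.cumsum(asort**2)])
    E = a.size

    def _ratio(delta: float) -> float:
        idx = int(np.searchsorted(asort, delta, side="right"))
        t = E - idx
        if t == 0:
            return np.inf
        tail1 = s1[E] - s1[idx]
        tail2 = s2[E] - s2[idx]
        l1 = tail1 - delta * t
        l2sq = tail2 - 2 * delta * tail1 + delta * delta * t
        if l2sq <= 0:
            return np.inf
        return l1 / np.sqrt(l2sq)

    lo, hi = 0.0, float(asort[-1])
    for _ in range(N_BISECT):
        delta = 0.5 * (lo + hi)
        if _ratio(delta) > lam:
            lo = delta
        else:
            hi = delta
    s = np.sign(v) * np.maximum(a - hi, 0.0)
    s[np.abs(s) < 1e-12 * a.max()] = 0.0  # clear bisection dust at tie points
    norm = np.linalg.norm(s)
    if norm == 0:
        # lam at (or numerically below) 1 with tied maxima: fall back to the
        # single largest coordinate, lowest index on ties.
        j = int(np.argmax(a))
        s = np.zeros_like(v)
        s[j] = np.sign(v[j])
        return s
    return s / norm


def sparse_pair(
    M: np.ndarray, spec: RegularizationSpec
) -> tuple[np.ndarray, np.ndarray, bool]:
    """L1-budgeted rank-1 weight pair by alternating soft-thresholded updates.

    Initialized at the unregularized leading pair; iterates
    wc <- S(M wp, lambda_c), wp <- S(M^T wc, lambda_p) until the largest
    entry change drops below 1e-8 (or 500 iterations, returning the last
    iterate with a warning).  Returns (wc, wp, converged).
    """
    M = np.asarray(M, dtype=float)
    spec.validate(M.shape[0], M.shape[1])
    if not np.any(M):
        raise ValueError("cross-covariance matrix is identically zero")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    # alternate from the leading pair; when the top of the spectrum is
    # nearly degenerate the fixed point can depend on the start, so the
    # near-degenerate pairs are tried too and the best objective kept
    starts = [j for j in range(s.size) if s[j] >= 0.9 * s[0]]
    best = None
    for j in starts:
        wc, wp = U[:, j], Vt[j, :]
        wp_prev2 = None
        converged = False
        cycling = False
        for _ in range(MAX_ITER):
            wc_new = soft_threshold_unit(M @ wp, spec.lambda_c)
            wp_new = soft_threshold_unit(M.T @ wc_new, spec.lambda_p)
            delta = max(np.max(np.abs(wc_new - wc)), np.max(np.abs(wp_new - wp)))
            # period-2 support oscillation: bail out early, flagged below
            if wp_prev2 is not None and np.max(np.abs(wp_new - wp_prev2)) < TOL and delta >= TOL:
                cycling = True
                wc, wp = wc_new, wp_new
                break
            wp_prev2 = wp
            wc, wp = wc_new, wp_new
            if delta < TOL:
                converged = True
                break
        obj = wc @ M @ wp
        if best is None or abs(obj) > best[0]:
            best = (abs(obj), wc, wp, converged, cycling)
    _, wc, wp, converged, cycling = best
    if not converged:
        warnings.warn(
            "sparse_pair did not converge"
            + (" (period-2 oscillation)" if cycling else "")
            + "; returning last iterate",
            stacklevel=2,
        )
    wc, wp = _orient(wc, wp, M)
    return wc, wp, converged


def deflate(
    C: np.ndarray, P: np.ndarray, phi: np.ndarray, psi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Projection deflation of each domain on its own latent scores."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if not np.any(phi) or not np.any(psi):
        raise ValueError("cannot deflate on a zero score vector")
    C_res = C - np.outer(phi, phi @ C) / (phi @ phi)
    P_res = P - np.outer(psi, psi @ P) / (psi @ psi)
    return C_res, P_res


@dataclass
class PLSComponent:
    """One rank-1 latent association between the two domains."""

    wc: np.ndarray
    wp: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    cov_score: float
    pct_cov: float
    converged: bool = True

    @property
    def wp_nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.wp)

    @property
    def wc_nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.wc)


def _fit_components(
    C: np.ndarray, P: np.ndarray, spec: RegularizationSpec, k: int
) -> tuple[list[PLSComponent], list[tuple[float, float]]]:
    components: list[PLSComponent] = []
    trace: list[tuple[float, float]] = []
    n = C.shape[0]
    Cr, Pr = C.copy(), P.copy()
    for _ in range(k):
        M = cross_covariance(Cr, Pr)
        wc, wp, converged = sparse_pair(M, spec)
        phi = Cr @ wc
        psi = Pr @ wp
        cov = phi @ psi / (n - 1)
        components.append(PLSComponent(wc, wp, phi, psi, cov, np.nan, converged))
        Cr, Pr = deflate(Cr, Pr, phi, psi)
        trace.append((float(np.linalg.norm(Cr)), float(np.linalg.norm(Pr))))
    ref = components[0].cov_score
    for comp in components:
        comp.pct_cov = 100.0 * comp.cov_score / ref if ref != 0 else np.nan
    return components, trace


def fit_rpls(
    C: np.ndarray, P: np.ndarray, spec: RegularizationSpec, k: int = 4
) -> "RPLSResults":
    """Fit k regularized PLS components on standardized domains.

    Each component solves the L1-budgeted covariance maximization on the
    cross-covariance of the current residuals; both domains are then
    projection-deflated on their own scores.  The covariance score of
    component j is cov(phi_j, psi_j), and pct_cov expresses it as a
    percentage of component 1's.
    """
    n, E = C.shape
    p = P.shape[1]
    kmax = min(E, p, n - 1)
    if not (1 <= k <= kmax):
        raise ValueError(f"k={k} outside [1, {kmax}] for n={n}, E={E}, p={p}")
    spec.validate(E, p)
    components, trace = _fit_components(C, P, spec, k)
    return RPLSResults(None, components, spec, trace, C=C, P=P)


def _component1_wc(C: np.ndarray, P: np.ndarray, lam_c: float, lam_p: float) -> np.ndarray:
    M = cross_covariance(C, P)
    wc, _, _ = sparse_pair(M, RegularizationSpec(lam_c, lam_p))
    return wc


def select_lambda_c(
    C: np.ndarray,
    P: np.ndarray,
    target_fraction: float = 0.5,
    n_grid: int = 50,
    lambda_p: float | None = None,
) -> float:
    """Connectivity budget preserving a target fraction of nonzero weights.

    Grid search over n_grid (>= 50) log-spaced budgets in [1, sqrt(E)];
    returns the budget whose component-1 w_c nonzero fraction is closest
    to ``target_fraction`` (ties favor the smaller budget, i.e. the
    stronger regularization).  The phenotype budget is held unregularized
    during the search unless given.
    """
    E = C.shape[1]
    if lambda_p is None:
        lambda_p = np.sqrt(P.shape[1])
    grid = np.geomspace(1.0, np.sqrt(E), max(n_grid, 50))
    best_lam, best_gap = grid[0], np.inf
    for lam in grid:
        wc = _component1_wc(C, P, lam, lambda_p)
        frac = np.count_nonzero(wc) / E
        gap = abs(frac - target_fraction)
        if gap < best_gap - 1e-15:
            best_gap, best_lam = gap, lam
    return float(best_lam)


def select_lambda_p(
    C: np.ndarray,
    P: np.ndarray,
    max_features: int = 3,
    n_grid: int = 100,
    lambda_c: float | None = None,
) -> float:
    """Weakest phenotype regularization keeping component 1 to few features.

    Scans >= 100 log-spaced budgets in [1, sqrt(p)] and returns the
    largest budget whose component-1 w_p has at most ``max_features``
    nonzero entries (a budget of 1 forces a single feature and is always
    feasible).
    """
    p = P.shape[1]
    if lambda_c is None:
        lambda_c = np.sqrt(C.shape[1])
    grid = np.geomspace(1.0, np.sqrt(p), max(n_grid, 100))
    best = grid[0]
    for lam in grid:
        _, wp, _ = sparse_pair(
            cross_covariance(C, P), RegularizationSpec(lambda_c, lam)
        )
        if np.count_nonzero(wp) <= max_features:
            best = lam
    return float(best)


class TripleNetworkPLS:
    """Regularized PLS model of connectivity–phenotype covariance.

    Parameters
    ----------
    connectivity : (n, E) array
        Per-participant TNM edge vectors (rows in participant order).
    phenotypes : (n, p) array or PhenotypeMatrix
        Standardized phenotypic domain.
    edge_mask : TNMEdgeMask, optional
        Edge bookkeeping; required for substrate inference downstream.
    phenotype_labels : sequence of str, optional
    standardize : bool
        Column-wise z-score both domains before fitting (default True).

    Examples
    --------
    >>> model = TripleNetworkPLS(C, P, edge_mask=mask)
    >>> res = model.fit(k=4)
    >>> res.summary()
    """

    def __init__(
        self,
        connectivity: np.ndarray,
        phenotypes,
        *,
        edge_mask=None,
        phenotype_labels=None,
        standardize: bool = True,
    ):
        from .phenotypes import PhenotypeMatrix

        if isinstance(phenotypes, PhenotypeMatrix):
            if phenotype_labels is None:
                phenotype_labels = phenotypes.column_labels
            phenotypes = phenotypes.values
        C_raw = np.asarray(connectivity, dtype=float)
        P_raw = np.asarray(phenotypes, dtype=float)
        if standardize:
            self.C, self.P = standardize_domains(C_raw, P_raw)
        else:
            self.C, self.P = C_raw, P_raw
        self.edge_mask = edge_mask
        if phenotype_labels is None:
            phenotype_labels = tuple(f"p{i}" for i in range(P_raw.shape[1]))
        self.phenotype_labels = tuple(phenotype_labels)

    @classmethod
    def from_connectomes(cls, connectomes, phenotypes, mask, **kwargs):
        """Build the connectivity domain by vectorizing FunctionalConnectomes."""
        from .atlas import vectorize

        C = np.vstack([vectorize(fc, mask).values for fc in connectomes])
        return cls(C, phenotypes, edge_mask=mask, **kwargs)

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @property
    def n_edges(self) -> int:
        return self.C.shape[1]

    def select_regularization(
        self, target_fraction: float = 0.5, max_features: int = 3
    ) -> RegularizationSpec:
        """Run both budget-selection rules on this model's domains."""
        lam_c = select_lambda_c(self.C, self.P, target_fraction)
        lam_p = select_lambda_p(self.C, self.P, max_features, lambda_c=lam_c)
        return RegularizationSpec(lam_c, lam_p)

    def fit(
        self,
        k: int = 4,
        lambda_c: float | None = None,
        lambda_p: float | None = None,
        target_fraction: float = 0.5,
        max_features: int = 3,
    ) -> "RPLSResults":
        """Fit k components, selecting any unspecified budget from the data."""
        if lambda_c is None:
            lambda_c = select_lambda_c(self.C, self.P, target_fraction)
        if lambda_p is None:
            lambda_p = select_lambda_p(self.C, self.P, max_features, lambda_c=lambda_c)
        spec = RegularizationSpec(float(lambda_c), float(lambda_p))
        res = fit_rpls(self.C, self.P, spec, k)
        res.model = self
        return res


class RPLSResults:
    """Fitted components of a :class:`TripleNetworkPLS` model."""

    def __init__(self, model, components, spec, deflation_trace, C=None, P=None):
        self.model = model
        self.components: list[PLSComponent] = components
        self.spec: RegularizationSpec = spec
        self.deflation_trace = deflation_trace
        self._C = C
        self._P = P

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def cov_scores(self) -> np.ndarray:
        return np.array([c.cov_score for c in self.components])

    @property
    def pct_cov(self) -> np.ndarray:
        return np.array([c.pct_cov for c in self.components])

    @property
    def Wc(self) -> np.ndarray:
        return np.column_stack([c.wc for c in self.components])

    @property
    def Wp(self) -> np.ndarray:
        return np.column_stack([c.wp for c in self.components])

    @property
    def phenotype_labels(self) -> tuple[str, ...]:
        if self.model is not None:
            return self.model.phenotype_labels
        return tuple(f"p{i}" for i in range(self.components[0].wp.size))

    def component_name(self, idx: int, top: int = 2) -> str:
        """Label a component by its top-|coefficient| phenotypes, joined by '/'."""
        wp = self.components[idx].wp
        order = np.argsort(-np.abs(wp), kind="stable")
        labels = self.phenotype_labels
        chosen = [labels[j] for j in order[:top] if wp[j] != 0]
        return "/".join(chosen) if chosen else "(empty)"

    # ---- downstream analyses -------------------------------------------

    def coefficient_matrix(self, component: int = 0) -> np.ndarray:
        """Symmetric region-by-region embedding of a component's w_c."""
        from .inference import to_matrix

        self._require_mask()
        return to_matrix(self.components[component].wc, self.model.edge_mask)

    def block_significance(self, component: int = 0, n_perm: int = 1000,
                           percentile: float = 99.0, seed=None):
        from .inference import null_block_significance

        self._require_mask()
        return null_block_significance(
            self.components[component].wc, self.model.edge_mask,
            n_perm=n_perm, percentile=percentile, seed=seed,
        )

    def strength_profile(self, component: int = 0, region_table=None):
        from .inference import signed_strength

        self._require_mask()
        return signed_strength(
            self.coefficient_matrix(component), self.model.edge_mask,
            region_table=region_table,
        )

    def circuit_summary(self, component: int = 0, n_perm: int = 1000,
                        percentile: float = 99.0, seed=None):
        from .inference import circuit_summary

        self._require_mask()
        sig = self.block_significance(component, n_perm, percentile, seed)
        return circuit_summary(self.components[component].wc, self.model.edge_mask, sig)

    def loocv(self, **kwargs):
        """Leave-one-out stability ensemble at this fit's regularization."""
        from .stability import loocv

        if self.model is None:
            raise ValueError("results are detached from their model")
        return loocv(self.model.C, self.model.P, self.spec, self.k,
                     phenotype_labels=self.phenotype_labels, **kwargs)

    def _require_mask(self):
        if self.model is None or self.model.edge_mask is None:
            raise ValueError("an edge mask is required; build the model with edge_mask=")

    # ---- reporting ------------------------------------------------------

    def summary(self) -> str:
        rows = []
        for i, comp in enumerate(self.components):
            rows.append(
                {
                    "component": i + 1,
                    "name": self.component_name(i),
                    "cov_score": comp.cov_score,
                    "pct_cov": comp.pct_cov,
                    "wc_nonzero": int(np.count_nonzero(comp.wc)),
                    "wp_nonzero": int(np.count_nonzero(comp.wp)),
                    "converged": comp.converged,
                }
            )
        df = pd.DataFrame(rows)
        header = (
            "Regularized PLS results\n"
            f"  n = {self.components[0].phi.size}, E = {self.components[0].wc.size}, "
            f"p = {self.components[0].wp.size}\n"
            f"  lambda_c = {self.spec.lambda_c:.4g}, lambda_p = {self.spec.lambda_p:.4g}\n"
        )
        return header + df.to_string(index=False, float_format=lambda x: f"{x:.4f}")

    def to_dict(self) -> dict:
        """JSON-serializable record: sparse w_c, dense w_p, scores, spec."""
        comps = []
        for comp in self.components:
            nz = comp.wc_nonzero
            comps.append(
                {
                    "wc_sparse": {int(i): float(comp.wc[i]) for i in nz},
                    "wc_length": int(comp.wc.size),
                    "wp": comp.wp.tolist(),
                    "phi": comp.phi.tolist(),
                    "psi": comp.psi.tolist(),
                    "cov_score": float(comp.cov_score),
                    "pct_cov": float(comp.pct_cov),
                    "converged": bool(comp.converged),
                }
            )
        return {
            "lambda_c": self.spec.lambda_c,
            "lambda_p": self.spec.lambda_p,
            "phenotype_labels": list(self.phenotype_labels),
            "components": comps,
            "deflation_trace": self.deflation_trace,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def plot_phenotype_coefficients(self, ax=None):
        """Bar chart of w_p per component (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        width = 0.8 / self.k
        x = np.arange(len(self.phenotype_labels))
        for i, comp in enumerate(self.components):
            ax.bar(x + i * width, comp.wp, width, label=self.component_name(i))
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(self.phenotype_labels, rotation=45, ha="right")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("phenotype coefficient")
        ax.legend(fontsize="small")
        return ax
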