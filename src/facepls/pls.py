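"""Two-block partial least squares (2B-PLS) by SVD of the cross-block covariance.

The model takes two matrices over the same objects -- here an instrumental
block B1 (n trials x p1 behavioural covariates) and a feature block B2
(n trials x p2 binary design indicators) -- and finds pairs of axes, one
per block, whose projected scores have maximal covariance.  Each pair is a
*latent structure*; there are K = min(p1, p2) of them.

Fitting is a one-shot singular value decomposition of the p1 x p2
cross-product of the column-preprocessed blocks (Tucker's inter-battery
factor analysis; in morphometrics the Rohlf-Corti two-block PLS).  For
this symmetric two-block case the iterative NIPALS-with-deflation scheme
converges to the same decomposition; the SVD route is deterministic and
directly testable, which is why it is used here.  The decomposition is
well defined when columns outnumber rows (p >> n) and when columns are
exact linear combinations of each other, situations a one-hot feature
block produces by construction.

Reported per structure: the singular value; its share of total squared
cross-block covariance (the scree quantity); the paired score vectors;
and *correlation loadings* -- the Pearson correlation of each original,
un-preprocessed variable with its own block's score -- together with a
significance mask at level alpha (two-sided t-test on r with n - 2
degrees of freedom, or a permutation alternative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import Block

__all__ = [
    "PLSDataError",
    "PreprocessingRecord",
    "preprocess",
    "variance_shares",
    "correlation_with_scores",
    "significance_mask",
    "critical_r",
    "PLS2B",
    "PLS2BResults",
]

ORTHO_TOL = 1e-10


class PLSDataError(ValueError):
    """Input data unusable for a 2B-PLS fit."""


@dataclass(frozen=True)
class PreprocessingRecord:
    """What :func:`preprocess` did to one block, for exact reproduction."""

    mode: str
    means: np.ndarray
    scales: np.ndarray
    constant_columns: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "constant_columns": list(self.constant_columns),
        }


def preprocess(
    matrix: np.ndarray,
    mode: Literal["center", "center_scale"] = "center_scale",
) -> tuple[np.ndarray, PreprocessingRecord]:
    """Column-wise centering, optionally followed by unit-variance scaling.

    Zero-variance columns are left centered (all zeros) and flagged in the
    returned record rather than raising: a constant indicator is a data
    feature the caller may want reported.  Sample standard deviation
    (ddof=1) is used, hence n >= 3 objects are required.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise PLSDataError("block must be a 2-D matrix")
    n = X.shape[0]
    if n < 3:
        raise PLSDataError(f"need at least 3 objects, got {n}")
    if np.isnan(X).any():
        raise PLSDataError("block contains missing values")
    if mode not in ("center", "center_scale"):
        raise ValueError(f"unknown preprocessing mode {mode!r}")

    means = X.mean(axis=0)
    Z = X - means
    sd = Z.std(axis=0, ddof=1)
    # columns constant up to floating-point round-off count as zero-variance
    tol = 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    is_const = sd <= tol
    Z[:, is_const] = 0.0
    constant = tuple(int(j) for j in np.flatnonzero(is_const))
    if mode == "center_scale":
        scales = np.where(is_const, 1.0, sd)
        Z = Z / scales
    else:
        scales = np.ones_like(sd)
    return Z, PreprocessingRecord(mode, means, scales, constant)


def variance_shares(singular_values: np.ndarray) -> np.ndarray:
    """Squared singular values normalised to sum to one (the scree shares)."""
    s = np.asarray(singular_values, dtype=float)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise PLSDataError("all singular values are zero; variance shares undefined")
    return s**2 / total


def correlation_with_scores(
    original: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each original variable with each score column.

    Returns ``(loadings, flagged)`` where ``flagged`` marks (variable,
    structure) cells whose correlation is undefined -- a constant variable
    or a degenerate (zero-variance) score -- and was set to 0.
    """
    X = np.asarray(original, dtype=float)
    T = np.asarray(scores, dtype=float)
    Xc = X - X.mean(axis=0)
    Tc = T - T.mean(axis=0)
    xsd = np.sqrt((Xc**2).sum(axis=0))
    tsd = np.sqrt((Tc**2).sum(axis=0))
    # variables/scores constant up to round-off have no defined correlation
    xzero = xsd <= 1e-12 * np.sqrt(X.shape[0]) * np.maximum(1.0, np.abs(X).max(axis=0))
    tzero = tsd <= 1e-12 * np.sqrt(T.shape[0]) * np.maximum(1.0, np.abs(T).max(axis=0))
    denom = np.outer(np.where(xzero, 0.0, xsd), np.where(tzero, 0.0, tsd))
    flagged = denom == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Tc) / denom
    r[flagged] = 0.0
    return np.clip(r, -1.0, 1.0), flagged


def _r_pvalues(r: np.ndarray, n_objects: int) -> np.ndarray:
    """Two-sided p-values for correlation coefficients, t with n-2 df."""
    r = np.asarray(r, dtype=float)
    df = n_objects - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(t, df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)  # |r| = 1: significant by convention
    return p


def significance_mask(
    corr_loadings: np.ndarray, n_objects: int, alpha: float = 0.05
) -> np.ndarray:
    """Boolean mask, true where a correlation loading is significant at alpha.

    Two-sided test of the null r = 0 via t = r * sqrt((n-2)/(1-r^2)) with
    n - 2 degrees of freedom.  This is the test behind the significance
    rectangle drawn on paired loading plots.
    """
    if n_objects < 4:
        raise PLSDataError(f"need at least 4 objects for the t-test, got {n_objects}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return _r_pvalues(corr_loadings, n_objects) <= alpha


def critical_r(n_objects: int, alpha: float = 0.05) -> float:
    """|r| above which a loading is significant: invert the t quantile relation."""
    df = n_objects - 2
    tcrit = stats.t.isf(alpha / 2.0, df)
    return float(tcrit / np.sqrt(df + tcrit**2))


class PLS2B:
    """Two-block PLS model of an instrumental and a feature block.

    Parameters
    ----------
    b1, b2
        The two blocks over identical objects in identical row order:
        :class:`~facepls.blocks.Block` instances, DataFrames (index = row
        ids), or plain arrays.
    mode
        Column preprocessing applied to *both* blocks before the
        decomposition: ``"center"`` or ``"center_scale"`` (default).
        Binary feature columns are scaled like any other column -- the
        unequal raw variances of a 0/1 block and an instrumental block
        are exactly why both blocks are brought to comparable scale.

    Examples
    --------
    >>> model = PLS2B(b1, b2)
    >>> res = model.fit()
    >>> res.variance_share[:4].sum()
    """

    def __init__(
        self,
        b1,
        b2,
        mode: Literal["center", "center_scale"] = "center_scale",
    ) -> None:
        self.x1, self.row_ids, self.col_names_b1 = _coerce_block(b1, "b1")
        self.x2, row_ids2, self.col_names_b2 = _coerce_block(b2, "b2")
        if self.x1.shape[0] != self.x2.shape[0]:
            raise PLSDataError(
                f"blocks have {self.x1.shape[0]} and {self.x2.shape[0]} rows; "
                "align them first"
            )
        if self.row_ids and row_ids2 and self.row_ids != row_ids2:
            raise PLSDataError("block row identifiers differ; align blocks first")
        self.mode = mode
        self.n_objects = self.x1.shape[0]

    @classmethod
    def from_blocks(
        cls, instrumental: Block, features: Block, mode: str = "center_scale"
    ) -> "PLS2B":
        return cls(instrumental, features, mode=mode)

    def fit(self) -> "PLS2BResults":
        """Fit by SVD of the cross-product of the preprocessed blocks.

        The left/right singular vectors are the (orthonormal) block weight
        matrices; scores are the preprocessed blocks projected on them.
        The sign of each structure is fixed so that the largest-magnitude
        element of the block-1 weight vector is positive, making the fit
        fully deterministic.
        """
        z1, rec1 = preprocess(self.x1, self.mode)
        z2, rec2 = preprocess(self.x2, self.mode)
        cross = z1.T @ z2
        u, s, vt = np.linalg.svd(cross, full_matrices=False)
        v = vt.T
        # deterministic sign convention, applied jointly to each axis pair
        for k in range(u.shape[1]):
            i = int(np.argmax(np.abs(u[:, k])))
            if u[i, k] < 0:
                u[:, k] = -u[:, k]
                v[:, k] = -v[:, k]
        t1 = z1 @ u
        t2 = z2 @ v
        corr1, flag1 = correlation_with_scores(self.x1, t1)
        corr2, flag2 = correlation_with_scores(self.x2, t2)
        return PLS2BResults(
            model=self,
            weights_b1=u,
            weights_b2=v,
            scores_b1=t1,
            scores_b2=t2,
            singular_values=s,
            corr_loadings_b1=corr1,
            corr_loadings_b2=corr2,
            undefined_loadings_b1=flag1,
            undefined_loadings_b2=flag2,
            preprocessing={
                "mode": self.mode,
                "algorithm": "svd-of-cross-product (inter-battery / two-block PLS)",
                "score_covariance_convention": "cov(t1_k, t2_k) = singular_value_k / (n - 1)",
                "b1": rec1.to_dict(),
                "b2": rec2.to_dict(),
            },
        )


def _coerce_block(b, name: str) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(b, Block):
        return np.asarray(b.matrix, float), list(b.row_ids), list(b.col_names)
    if isinstance(b, pd.DataFrame):
        return b.to_numpy(float), [str(i) for i in b.index], [str(c) for c in b.columns]
    arr = np.asarray(b, dtype=float)
    if arr.ndim != 2:
        raise PLSDataError(f"{name} must be 2-D")
    return arr, [], [f"{name}_var{j}" for j in range(arr.shape[1])]


@dataclass
class PLS2BResults:
    """Fitted 2B-PLS decomposition.

    Attributes follow the block naming of the model: ``weights_b1`` is the
    p1 x K orthonormal weight (loading) matrix of the instrumental block,
    ``scores_b1 = Z1 @ weights_b1`` its n x K score matrix, and similarly
    for block 2.  ``corr_loadings_*`` are the correlation loadings of the
    original (un-preprocessed) variables with their own block's scores.
    """

    model: PLS2B
    weights_b1: np.ndarray
    weights_b2: np.ndarray
    scores_b1: np.ndarray
    scores_b2: np.ndarray
    singular_values: np.ndarray
    corr_loadings_b1: np.ndarray
    corr_loadings_b2: np.ndarray
    undefined_loadings_b1: np.ndarray
    undefined_loadings_b2: np.ndarray
    preprocessing: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        """Number of latent structures: min(p1, p2)."""
        return int(self.singular_values.shape[0])

    @property
    def n_objects(self) -> int:
        return self.model.n_objects

    @property
    def variance_share(self) -> np.ndarray:
        """Share of total squared cross-block covariance per structure."""
        return variance_shares(self.singular_values)

    @property
    def score_covariances(self) -> np.ndarray:
        """cov(scores_b1[:, k], scores_b2[:, k]) = singular_value_k / (n - 1)."""
        return self.singular_values / (self.n_objects - 1)

    def sig_mask_b1(self, alpha: float = 0.05) -> np.ndarray:
        return significance_mask(self.corr_loadings_b1, self.n_objects, alpha)

    def sig_mask_b2(self, alpha: float = 0.05) -> np.ndarray:
        return significance_mask(self.corr_loadings_b2, self.n_objects, alpha)

    def critical_r(self, alpha: float = 0.05) -> float:
        """|r| delimiting the significance rectangle on loading plots."""
        return critical_r(self.n_objects, alpha)

    # ---------------------------------------------------------------- permutation
    def permutation_loading_pvalues(
        self, n_permutations: int = 999, seed: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Permutation p-values for the correlation loadings of both blocks.

        Rows of block 2 are shuffled (destroying the block pairing), the
        model refitted, and per-entry p-values computed as the fraction of
        permutations whose |loading| meets or exceeds the observed one,
        with the usual +1 correction.
        """
        rng = np.random.default_rng(seed)
        z1, _ = preprocess(self.model.x1, self.model.mode)
        z2, _ = preprocess(self.model.x2, self.model.mode)
        obs1 = np.abs(self.corr_loadings_b1)
        obs2 = np.abs(self.corr_loadings_b2)
        exceed1 = np.zeros_like(obs1)
        exceed2 = np.zeros_like(obs2)
        n = z1.shape[0]
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            u, s, vt = np.linalg.svd(z1.T @ z2[perm], full_matrices=False)
            t1 = z1 @ u
            t2 = z2[perm] @ vt.T
            r1, _ = correlation_with_scores(self.model.x1, t1)
            r2, _ = correlation_with_scores(self.model.x2[perm], t2)
            exceed1 += np.abs(r1) >= obs1
            exceed2 += np.abs(r2) >= obs2
        p1 = (1.0 + exceed1) / (n_permutations + 1.0)
        p2 = (1.0 + exceed2) / (n_permutations + 1.0)
        return p1, p2

    def permutation_null_shares(
        self, n_permutations: int = 999, seed: int | None = None
    ) -> np.ndarray:
        """Null distribution of the first variance share under row shuffling.

        Returns the first variance share from ``n_permutations`` refits in
        which the rows of block 2 are randomly permuted.  Comparing the
        observed first share against this distribution calibrates how much
        apparent structure pure chance produces.
        """
        rng = np.random.default_rng(seed)
        z1, _ = preprocess(self.model.x1, self.model.mode)
        z2, _ = preprocess(self.model.x2, self.model.mode)
        n = z1.shape[0]
        out = np.empty(n_permutations)
        for b in range(n_permutations):
            s = np.linalg.svd(z1.T @ z2[rng.permutation(n)], compute_uv=False)
            out[b] = variance_shares(s)[0]
        return out

    # ---------------------------------------------------------------- reporting
    def scree_table(self) -> pd.DataFrame:
        """(structure index, variance share) table for the scree plot."""
        return pd.DataFrame(
            {
                "structure": np.arange(1, self.k + 1),
                "singular_value": self.singular_values,
                "variance_share": self.variance_share,
            }
        )

    def loadings_table(
        self, pair: tuple[int, int] = (1, 2), alpha: float = 0.05
    ) -> pd.DataFrame:
        """Plot-ready paired correlation loadings for two structures.

        One row per variable of both blocks, with the loadings on the two
        requested structures (1-based), the block of origin, and the
        significance of each loading at ``alpha``.
        """
        a, b = pair
        if not (1 <= a <= self.k and 1 <= b <= self.k):
            raise ValueError(f"structure pair {pair} out of range 1..{self.k}")
        m1a, m1b = self.sig_mask_b1(alpha)[:, a - 1], self.sig_mask_b1(alpha)[:, b - 1]
        m2a, m2b = self.sig_mask_b2(alpha)[:, a - 1], self.sig_mask_b2(alpha)[:, b - 1]
        rows = []
        for i, name in enumerate(self.model.col_names_b1):
            rows.append(
                {
                    "variable": name,
                    "block": 1,
                    f"loading_s{a}": self.corr_loadings_b1[i, a - 1],
                    f"loading_s{b}": self.corr_loadings_b1[i, b - 1],
                    f"significant_s{a}": bool(m1a[i]),
                    f"significant_s{b}": bool(m1b[i]),
                }
            )
        for i, name in enumerate(self.model.col_names_b2):
            rows.append(
                {
                    "variable": name,
                    "block": 2,
                    f"loading_s{a}": self.corr_loadings_b2[i, a - 1],
                    f"loading_s{b}": self.corr_loadings_b2[i, b - 1],
                    f"significant_s{a}": bool(m2a[i]),
                    f"significant_s{b}": bool(m2b[i]),
                }
            )
        return pd.DataFrame(rows)

    def summary(self, n_structures: int | None = None, alpha: float = 0.05) -> str:
        """Plain-text summary of the fitted decomposition."""
        k = n_structures or min(self.k, 10)
        share = self.variance_share
        cum = np.cumsum(share)
        lines = [
            "Two-block PLS (SVD of cross-block covariance)",
            "=" * 54,
            f"objects:            {self.n_objects}",
            f"block 1 (p1):       {self.model.x1.shape[1]} variables",
            f"block 2 (p2):       {self.model.x2.shape[1]} variables",
            f"latent structures:  {self.k}",
            f"preprocessing:      {self.preprocessing.get('mode', '?')}",
            f"critical |r| (alpha={alpha:g}): {self.critical_r(alpha):.4f}",
            "",
            f"{'structure':>9}  {'singular value':>14}  {'share':>7}  {'cumulative':>10}",
        ]
        for i in range(k):
            lines.append(
                f"{i + 1:>9}  {self.singular_values[i]:>14.4f}  "
                f"{share[i]:>6.1%}  {cum[i]:>9.1%}"
            )
        if k < self.k:
            lines.append(f"{'...':>9}  ({self.k - k} further structures)")
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        """Model dump: JSON metadata plus TSV matrices.

        Writes ``model.json`` (preprocessing record, singular values,
        variance shares), ``scree.tsv``, and one TSV per matrix (weights,
        scores, correlation loadings, significance masks at alpha 0.05).
        """
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "n_objects": self.n_objects,
            "k": self.k,
            "p1": self.model.x1.shape[1],
            "p2": self.model.x2.shape[1],
            "singular_values": self.singular_values.tolist(),
            "variance_share": self.variance_share.tolist(),
            "preprocessing": self.preprocessing,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        self.scree_table().to_csv(d / "scree.tsv", sep="\t", index=False, float_format="%.10g")
        scols = [f"s{i + 1}" for i in range(self.k)]

        def _tsv(mat, index, name):
            pd.DataFrame(np.asarray(mat), index=index, columns=scols).to_csv(
                d / name, sep="\t", index_label="name", float_format="%.10g"
            )

        rows = self.model.row_ids or [str(i) for i in range(self.n_objects)]
        _tsv(self.weights_b1, self.model.col_names_b1, "weights_b1.tsv")
        _tsv(self.weights_b2, self.model.col_names_b2, "weights_b2.tsv")
        _tsv(self.scores_b1, rows, "scores_b1.tsv")
        _tsv(self.scores_b2, rows, "scores_b2.tsv")
        _tsv(self.corr_loadings_b1, self.model.col_names_b1, "corr_loadings_b1.tsv")
        _tsv(self.corr_loadings_b2, self.model.col_names_b2, "corr_loadings_b2.tsv")
        _tsv(self.sig_mask_b1().astype(int), self.model.col_names_b1, "sig_mask_b1.tsv")
        _tsv(self.sig_mask_b2().astype(int), self.model.col_names_b2, "sig_mask_b2.tsv")

    # ---------------------------------------------------------------- plotting
    def plot_scree(self, ax=None):
        """Scree curve of variance shares (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.scree_table()
        ax.plot(t["structure"], t["variance_share"], marker="o")
        ax.set_xlabel("latent structure")
        ax.set_ylabel("share of total variance")
        ax.set_xticks(t["structure"])
        return ax

    def plot_loadings(self, pair: tuple[int, int] = (1, 2), alpha: float = 0.05, ax=None):
        """Paired correlation-loading scatter with the significance rectangle."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        a, b = pair
        tab = self.loadings_table(pair, alpha)
        for blk, colour in ((1, "black"), (2, "tab:blue")):
            sub = tab[tab["block"] == blk]
            ax.scatter(sub[f"loading_s{a}"], sub[f"loading_s{b}"], s=12, c=colour,
                       label=f"block {blk}")
        rc = self.critical_r(alpha)
        ax.add_patch(
            __import__("matplotlib.patches", fromlist=["Rectangle"]).Rectangle(
                (-rc, -rc), 2 * rc, 2 * rc, fill=False, ls="--", ec="red"
            )
        )
        share = self.variance_share
        ax.set_xlabel(f"structure {a} ({share[a - 1]:.1%} of total variance)")
        ax.set_ylabel(f"structure {b} ({share[b - 1]:.1%} of total variance)")
        ax.axhline(0, lw=0.5, c="grey")
        ax.axvline(0, lw=0.5, c="grey")
        ax.legend()
        return ax
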