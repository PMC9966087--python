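"""PCA morphospace over normalized elliptic-Fourier coefficients.

Each specimen's normalized coefficient set becomes one row of a feature
matrix (constant columns a1, b1, c1 dropped); principal component
analysis of the covariance matrix (not the correlation matrix — all
coefficients already share one normalized scale) yields the morphospace
in which occupation statistics are computed.  The decomposition uses a
deterministic symmetric eigensolver with a fixed sign convention, so
repeated runs are bit-identical.

The number of "effective" principal components — those treated as
carrying real shape signal — is selected by a configurable rule; the
default keeps every PC explaining at least 2 % of total variance, the
alternative keeps eigenvalues above their mean (Kaiser-style).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .efa import (
    EFACoefficients,
    efa_reconstruct,
    feature_vector,
    feature_vector_to_coeffs,
)
from .outlines import OutlineContour

__all__ = [
    "EffectivePcRule",
    "MorphospaceModel",
    "fit_morphospace",
    "effective_pcs",
    "reconstruct_along_pc",
    "coefficient_matrix",
]


class EffectivePcRule:
    """Rule selecting how many leading PCs count as effective.

    Use :meth:`gt_mean` (eigenvalues strictly above their mean) or
    :meth:`proportion_ge` (variance share at least ``threshold``).
    """

    def __init__(self, kind: str, threshold: float | None = None):
        if kind not in ("gt_mean", "proportion_ge"):
            raise ValueError(f"unknown effective-PC rule: {kind!r}")
        if kind == "proportion_ge":
            if threshold is None or not (0.0 < threshold < 1.0):
                raise ValueError("proportion_ge needs a threshold in (0, 1)")
        self.kind = kind
        self.threshold = threshold

    @classmethod
    def gt_mean(cls) -> "EffectivePcRule":
        return cls("gt_mean")

    @classmethod
    def proportion_ge(cls, threshold: float = 0.02) -> "EffectivePcRule":
        return cls("proportion_ge", threshold)

    def __repr__(self) -> str:
        if self.kind == "proportion_ge":
            return f"EffectivePcRule.proportion_ge({self.threshold})"
        return "EffectivePcRule.gt_mean()"


DEFAULT_PC_RULE = EffectivePcRule.proportion_ge(0.02)


def effective_pcs(eigenvalues: np.ndarray, rule: EffectivePcRule = DEFAULT_PC_RULE) -> int:
    """Count effective PCs from a descending non-negative eigenvalue vector."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue vector")
    if np.any(ev < -1e-12 * max(ev.max(initial=0.0), 1.0)):
        raise ValueError("eigenvalues must be non-negative")
    if np.any(np.diff(ev) > 1e-12 * max(ev.max(initial=0.0), 1.0)):
        raise ValueError("eigenvalues must be sorted descending")
    total = ev.sum()
    if total <= 0.0:
        return 0
    if rule.kind == "gt_mean":
        return int(np.sum(ev > ev.mean()))
    return int(np.sum(ev / total >= rule.threshold))


@dataclass(frozen=True)
class MorphospaceModel:
    """A fitted PCA morphospace.

    ``eigenvectors`` is ``(n_features, n_components)`` with orthonormal
    columns; ``scores`` is ``(n_specimens, n_components)``; eigenvalues
    are sample variances (ddof=1) along each PC, sorted descending.
    """

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    n_effective: int
    variance_explained: np.ndarray
    specimen_ids: tuple[str, ...] = ()
    structure_class: str | None = None

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def project(self, features: np.ndarray) -> np.ndarray:
        """Project feature row(s) into PC coordinates."""
        return (np.atleast_2d(features) - self.mean) @ self.eigenvectors

    def back_project(self, scores: np.ndarray) -> np.ndarray:
        """Map PC coordinates back to feature space."""
        return self.mean + np.atleast_2d(scores) @ self.eigenvectors.T

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mean": self.mean.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_effective": self.n_effective,
            "variance_explained": self.variance_explained.tolist(),
            "specimen_ids": list(self.specimen_ids),
            "structure_class": self.structure_class,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def coefficient_matrix(coeff_sets: list[EFACoefficients]) -> np.ndarray:
    """Stack normalized coefficient sets into a PCA feature matrix."""
    rows = [feature_vector(c) for c in coeff_sets]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"unequal coefficient-vector lengths: {sorted(lengths)}")
    return np.vstack(rows)


def fit_morphospace(
    coeff_matrix: np.ndarray,
    pc_rule: EffectivePcRule = DEFAULT_PC_RULE,
    *,
    specimen_ids: tuple[str, ...] | list[str] = (),
    structure_class: str | None = None,
) -> MorphospaceModel:
    """Covariance PCA of a specimens x features coefficient matrix.

    Eigenvector signs follow the convention that the largest-magnitude
    loading of each PC is positive, making results reproducible across
    runs and BLAS builds.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"coefficient matrix must be 2-D, got shape {X.shape}")
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need >= 3 specimens, got {n}")
    if specimen_ids and len(specimen_ids) != n:
        raise ValueError("specimen_ids length mismatch")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading of each PC positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    scores = Xc @ evecs
    total = evals.sum()
    var_exp = evals / total if total > 0 else np.zeros_like(evals)
    return MorphospaceModel(
        mean=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        scores=scores,
        n_effective=effective_pcs(evals, pc_rule),
        variance_explained=var_exp,
        specimen_ids=tuple(specimen_ids),
        structure_class=structure_class,
    )


def reconstruct_along_pc(
    model: MorphospaceModel,
    pc: int,
    k_sd: float,
    *,
    n_points: int = 256,
) -> OutlineContour:
    """Outline at ``mean + k_sd * sqrt(eigenvalue) * eigenvector`` of a PC.

    Used to read the shape meaning of a PC's extremes (e.g. slender vs
    broad head capsules at -2 SD vs +2 SD).  ``pc`` is 1-based.
    """
    if not (1 <= pc <= model.n_components):
        raise ValueError(f"pc must be in 1..{model.n_components}, got {pc}")
    vec = model.mean + k_sd * np.sqrt(model.eigenvalues[pc - 1]) * model.eigenvectors[:, pc - 1]
    coeffs = feature_vector_to_coeffs(vec)
    return efa_reconstruct(coeffs, n_points=n_points)
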