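"""Mutational-signature exposure refitting by non-negative least squares.

Exposures for a mutation set are obtained by projecting its 96-channel
trinucleotide-context spectrum onto a user-supplied reference signature
matrix (channels x signatures) under a non-negativity constraint, then
normalizing to sum 1. Clonal and subclonal mutation sets are fitted
separately; any set with fewer than 15 mutations is skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

MIN_MUTATIONS = 15
N_CHANNELS = 96


@dataclass
class SignatureFit:
    exposures: dict[str, np.ndarray] = field(default_factory=dict)
    residuals: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    signatures: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exposures, index=self.signatures).T


def fit_exposures(spectrum: np.ndarray, signature_matrix: np.ndarray
                  ) -> tuple[np.ndarray, float]:
    """NNLS fit of one 96-channel spectrum; returns (weights, residual).

    Weights are normalized to sum 1; the residual is the L2 norm of the
    reconstruction error of the *frequency* spectrum.
    """
    if signature_matrix.shape[0] != N_CHANNELS:
        raise ValueError(
            f"signature matrix must have {N_CHANNELS} rows, got "
            f"{signature_matrix.shape[0]}")
    total = spectrum.sum()
    freq = spectrum / total if total > 0 else spectrum
    w, _ = nnls(signature_matrix, freq)
    s = w.sum()
    if s > 0:
        w = w / s
    resid = float(np.linalg.norm(signature_matrix @ w - freq))
    return w, resid


def fit_signatures(context_counts: dict[str, np.ndarray],
                   signature_matrix: np.ndarray,
                   signature_names: list[str] | None = None) -> SignatureFit:
    """Fit exposures per mutation set (e.g. {"clonal": ..., "subclonal": ...}).

    ``context_counts`` maps a set label to its 96-channel count vector;
    sets with fewer than MIN_MUTATIONS total mutations are skipped with a
    warning.
    """
    if signature_names is None:
        signature_names = [f"S{i + 1}" for i in
                           range(signature_matrix.shape[1])]
    fit = SignatureFit(signatures=list(signature_names))
    for label, counts in context_counts.items():
        counts = np.asarray(counts, float)
        if counts.shape != (N_CHANNELS,):
            raise ValueError(f"{label}: spectrum must have {N_CHANNELS} "
                             "channels")
        if counts.sum() < MIN_MUTATIONS:
            warnings.warn(f"signature fit skipped for '{label}': "
                          f"{int(counts.sum())} < {MIN_MUTATIONS} mutations")
            fit.skipped.append(label)
            continue
        w, resid = fit_exposures(counts, signature_matrix)
        fit.exposures[label] = w
        fit.residuals[label] = resid
    return fit
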