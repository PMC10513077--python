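"""Plate-reader chemistry calculations and the single-cell QC filter.

Implements the study's kinetic-read urine/plasma chemistry arithmetic:

* blood urea nitrogen (BUN) signal ``((A60 − A120) − blank) · 0.467``,
* creatinine signal ``((A120 − A60) − blank)``,
* concentrations by linear regression through the standard curve,
* albumin-to-creatinine ratio (ACR, µg albumin per mg creatinine),
* glucose-dependent urine dilution selection for the albumin ELISA,
* the droplet QC rule: keep cells with mitochondrial read fraction < 40%
  and more than 200 expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BUN_FACTOR",
    "QCRule",
    "bun_signal",
    "crea_signal",
    "StandardCurve",
    "standard_curve_fit",
    "acr",
    "select_dilution",
    "qc_filter",
]

BUN_FACTOR = 0.467


def bun_signal(a60: float, a120: float, blank: float, factor: float = BUN_FACTOR):
    """Blanked kinetic BUN signal: ((A60 − A120) − blank) · factor."""
    return ((np.asarray(a60) - np.asarray(a120)) - blank) * factor


def crea_signal(a60: float, a120: float, blank: float):
    """Blanked kinetic creatinine signal: ((A120 − A60) − blank)."""
    return (np.asarray(a120) - np.asarray(a60)) - blank


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line signal = slope·concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def concentration(self, signal):
        """Invert the fitted line to read off concentrations."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


def standard_curve_fit(concentrations, signals) -> StandardCurve:
    """Fit a linear standard curve by least squares.

    Raises
    ------
    ValueError
        Fewer than two standards, or degenerate (constant) concentrations.
    """
    c = np.asarray(concentrations, dtype=float)
    s = np.asarray(signals, dtype=float)
    if c.size < 2 or c.size != s.size:
        raise ValueError("need >= 2 matched standards")
    if np.ptp(c) == 0:
        raise ValueError("degenerate standards: all concentrations equal")
    res = sps.linregress(c, s)
    if res.slope == 0:
        raise ValueError("degenerate standards: zero slope")
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def acr(albumin_ug_per_dl, creatinine_mg_per_dl):
    """Albumin-to-creatinine ratio, µg albumin per mg creatinine."""
    crea = np.asarray(creatinine_mg_per_dl, dtype=float)
    if np.any(crea <= 0):
        raise ZeroDivisionError("creatinine must be positive")
    return np.asarray(albumin_ug_per_dl, dtype=float) / crea


def select_dilution(blood_glucose_mg_per_dl: float) -> int:
    """Urine dilution factor for the albumin ELISA, by blood glucose.

    < 200 mg/dL -> 1:150; 200–350 mg/dL (inclusive) -> 1:250;
    > 350 mg/dL -> 1:500.
    """
    g = float(blood_glucose_mg_per_dl)
    if g < 0:
        raise ValueError("glucose must be nonnegative")
    if g < 200.0:
        return 150
    if g <= 350.0:
        return 250
    return 500


@dataclass(frozen=True)
class QCRule:
    """Droplet QC thresholds (mito fraction strict <, gene count strict >)."""

    max_mito_fraction: float = 0.40
    min_genes: int = 200
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_mito_fraction < 1.0):
            raise ValueError("max_mito_fraction must be in (0, 1)")


def qc_filter(counts, gene_names, rule: QCRule = QCRule()):
    """Apply the mitochondrial-fraction / gene-count QC filter.

    Parameters
    ----------
    counts : (cells, genes) array-like of nonnegative counts
    gene_names : sequence of gene symbols; mitochondrial genes are
        recognised by a case-insensitive name prefix (mouse ``mt-``).
    rule : QCRule

    Returns
    -------
    keep : boolean array over cells
    n_kept : int
    """
    x = np.asarray(counts)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("counts must be a nonempty cells x genes matrix")
    names = [str(g) for g in gene_names]
    if len(names) != x.shape[1]:
        raise ValueError("gene_names length must match the gene axis")
    prefix = rule.mito_prefix.lower()
    is_mito = np.array([g.lower().startswith(prefix) for g in names])
    totals = x.sum(axis=1).astype(float)
    mito = x[:, is_mito].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 1.0)  # empty cell fails
    genes_expr = (x > 0).sum(axis=1)
    keep = (frac < rule.max_mito_fraction) & (genes_expr > rule.min_genes)
    return keep, int(keep.sum())
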