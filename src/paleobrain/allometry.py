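"""Cranial-capacity conversion and relative brain size (residuals).

Relative brain size (encephalization) is the residual of log10 brain mass
from the allometric regression on log10 body mass.  Because the regression
line is fitted on a particular unit scale, absolute residual values shift
by a constant when masses change units (for a fixed slope); differences of
residuals between two taxa or nodes are unit-invariant, and all downstream
statistics in this package use such differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Standard primate cranial-capacity / brain-mass conversion (Martin 1981):
# log10(cranial capacity, cm^3) = 1.018 * log10(brain mass, g) - 0.025
CC_SLOPE = 1.018
CC_INTERCEPT = -0.025


@dataclass(frozen=True)
class AllometryLine:
    """A fitted log-log brain~body line with explicit unit conventions."""

    intercept: float
    slope: float
    brain_unit: str = "g"
    body_unit: str = "g"

    def predict(self, log10_body):
        return self.intercept + self.slope * np.asarray(log10_body, float)

    @classmethod
    def from_fit(cls, fit, brain_unit="g", body_unit="g"):
        return cls(intercept=float(fit.intercept), slope=float(fit.slope),
                   brain_unit=brain_unit, body_unit=body_unit)


@dataclass(frozen=True)
class RelativeBrainValue:
    entity: object              # taxon label or node id
    residual: float             # log10 units, observed - predicted


def cranial_capacity_from_brain_mass(brain_mass_g):
    """Cranial capacity (cm^3) from brain mass (g)."""
    m = np.asarray(brain_mass_g, float)
    if np.any(m <= 0):
        raise ValueError("brain mass must be positive")
    out = 10.0 ** (CC_SLOPE * np.log10(m) + CC_INTERCEPT)
    return float(out) if np.isscalar(brain_mass_g) else out


def brain_mass_from_cranial_capacity(cc_cm3):
    """Exact inverse of :func:`cranial_capacity_from_brain_mass`."""
    cc = np.asarray(cc_cm3, float)
    if np.any(cc <= 0):
        raise ValueError("cranial capacity must be positive")
    out = 10.0 ** ((np.log10(cc) - CC_INTERCEPT) / CC_SLOPE)
    return float(out) if np.isscalar(cc_cm3) else out


def residual(log10_brain, log10_body, line):
    """Relative brain size: observed minus allometrically predicted log mass."""
    return np.asarray(log10_brain, float) - line.predict(log10_body)


def tip_residuals(traits, line):
    """Residuals for every taxon in a trait table, as a pandas Series."""
    d = traits.data
    return pd.Series(residual(d["log10_brain"], d["log10_body"], line),
                     index=d.index, name="residual")


def ancestral_relative(method, tree, traits, line, asr=None, taxa=None):
    """Ancestral relative brain size by either of two pipelines.

    ``residuals_second``: reconstruct brain and body separately, then take
    the residual of the reconstructed values at each node from the extant-
    fitted line.  ``residuals_first``: compute tip residuals first, then
    reconstruct the residuals themselves.

    Parameters
    ----------
    method : {"residuals_first", "residuals_second"}
    asr : callable, optional
        ``asr(tree, values_by_taxon) -> DataFrame['estimate']``; defaults to
        the ML reconstruction.

    Returns a Series of node residuals indexed by internal node id.
    """
    from .reconstruct import asr_ml

    if asr is None:
        asr = lambda t, v: asr_ml(t, v)
    taxa = list(taxa) if taxa is not None else traits.taxa
    d = traits.data.loc[taxa]
    if method == "residuals_second":
        brain = asr(tree, dict(zip(taxa, d["log10_brain"])))["estimate"]
        body = asr(tree, dict(zip(taxa, d["log10_body"])))["estimate"]
        vals = residual(brain.to_numpy(), body.to_numpy(), line)
        return pd.Series(vals, index=brain.index, name="residual")
    if method == "residuals_first":
        res = residual(d["log10_brain"].to_numpy(),
                       d["log10_body"].to_numpy(), line)
        est = asr(tree, dict(zip(taxa, res)))["estimate"]
        return pd.Series(est.to_numpy(), index=est.index, name="residual")
    raise ValueError("method must be 'residuals_first' or 'residuals_second'")
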