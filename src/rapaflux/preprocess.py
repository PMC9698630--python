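"""Normalization and quality filtering of metabolite intensity matrices.

All multivariate stages expect intensities on a comparable scale; the default
pipeline log10-transforms the raw (nonnegative) intensities and autoscales
each metabolite to zero mean / unit sample variance, the usual preparation
for PCA and PLS-DA of GC-MS abundance data.  Pareto scaling (divide by the
square root of the standard deviation) is available for workflows that want
to damp rather than remove magnitude differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ParameterError, ValidationError
from .synthgen import MetaboliteDataset

TRANSFORMS = ("log10", "none")
SCALINGS = ("autoscale", "pareto", "none")
MISSING_POLICIES = ("half_min_impute", "drop_metabolite")


@dataclass(frozen=True)
class NormalizationConfig:
    transform: str = "log10"
    scaling: str = "autoscale"
    missing_policy: str = "half_min_impute"
    missing_threshold: float = 0.5

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ParameterError(f"unknown transform '{self.transform}'")
        if self.scaling not in SCALINGS:
            raise ParameterError(f"unknown scaling '{self.scaling}'")
        if self.missing_policy not in MISSING_POLICIES:
            raise ParameterError(f"unknown missing_policy '{self.missing_policy}'")
        if not 0.0 <= self.missing_threshold <= 1.0:
            raise ParameterError("missing_threshold must lie in [0, 1]")


def normalize(ds: MetaboliteDataset,
              cfg: NormalizationConfig | None = None) -> MetaboliteDataset:
    """Transform and scale every metabolite column; see NormalizationConfig.

    Zeros count as missing values: a column whose missing fraction exceeds
    ``missing_threshold`` is dropped under the ``drop_metabolite`` policy;
    otherwise zeros are replaced by half the column's minimum positive value
    before a log transform.  Constant columns cannot be autoscaled and are
    set to zero with a warning.  Sample standard deviation (n-1) throughout.
    """
    cfg = cfg if cfg is not None else NormalizationConfig()
    ds.validate()
    X = ds.intensities.copy().astype(float)
    if X.shape[0] < 2:
        raise EmptyInputError("normalization needs at least 2 samples")
    if (X.to_numpy() < 0).any():
        raise ValidationError("negative intensities; normalize expects raw data")

    missing_frac = (X == 0).mean(axis=0)
    drop: list[str] = []
    for met in X.columns:
        col = X[met]
        n_zero = int((col == 0).sum())
        if n_zero == 0:
            continue
        if (cfg.missing_policy == "drop_metabolite"
                and missing_frac[met] > cfg.missing_threshold):
            drop.append(met)
            continue
        positive = col[col > 0]
        if positive.empty:
            warnings.warn(f"metabolite '{met}' is all-zero; dropped")
            drop.append(met)
            continue
        X[met] = col.replace(0.0, positive.min() / 2.0)
    if drop:
        X = X.drop(columns=drop)
        if X.shape[1] == 0:
            raise EmptyInputError("all metabolites dropped during normalization")

    if cfg.transform == "log10":
        X = np.log10(X)

    if cfg.scaling != "none":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        centered = X - mean
        if cfg.scaling == "autoscale":
            constant = sd == 0
            if constant.any():
                warnings.warn(
                    f"constant metabolites set to 0 under autoscale: "
                    f"{list(sd.index[constant])}")
            denom = sd.replace(0.0, np.inf)
            X = centered / denom
        else:  # pareto
            denom = np.sqrt(sd).replace(0.0, np.inf)
            X = centered / denom

    out = MetaboliteDataset(
        intensities=X,
        metadata=ds.metadata.loc[X.index].copy(),
        platform=ds.platform,
        normalized=cfg.transform != "none" or cfg.scaling != "none",
    )
    out.validate()
    return out
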