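"""Weighted metabolite co-response network: adjacency, topological overlap,
module detection, eigenprofiles and module-treatment association.

The workflow mirrors weighted correlation network analysis: soft-threshold
the metabolite-metabolite Pearson correlation into an adjacency
(``|r|^beta`` unsigned, ``((1+r)/2)^beta`` signed), convert it to the
topological overlap similarity

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

cluster 1 - TOM by average linkage with a static height cut, summarize each
module by the first principal component of its standardized member profiles
(the eigenprofile), and correlate eigenprofiles with binary treatment
indicators.  A module is "selected" for a treatment when r > r_cut and the
two-sided Student-t p-value < p_cut (strict inequalities), the selection
rule used for the elicitor modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .exceptions import EmptyInputError, ParameterError, ValidationError

GREY = "grey"


@dataclass(frozen=True)
class NetworkConfig:
    power: int = 9                      # unsigned-network default for < 20 samples
    network_type: str = "unsigned"      # "unsigned" | "signed"
    min_module_size: int = 3
    cut_height: float = 0.9             # static cut on 1 - TOM
    r_cut: float = 0.65
    p_cut: float = 0.01

    def __post_init__(self):
        if self.power < 1:
            raise ParameterError("power must be >= 1")
        if self.network_type not in ("unsigned", "signed"):
            raise ParameterError(f"unknown network_type '{self.network_type}'")
        if not 0.0 < self.cut_height <= 1.0:
            raise ParameterError("cut_height must lie in (0, 1]")
        if not 0.0 < self.r_cut < 1.0:
            raise ParameterError("r_cut must lie in (0, 1)")
        if not 0.0 < self.p_cut < 1.0:
            raise ParameterError("p_cut must lie in (0, 1)")


@dataclass
class ModuleSet:
    assignment: pd.Series                       # metabolite -> module label
    eigenprofiles: pd.DataFrame = None          # modules x samples
    trait_correlation: pd.DataFrame = None      # module, trait, r, p, selected
    selected: dict[str, str] = field(default_factory=dict)

    def members(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    def module_labels(self) -> list[str]:
        return [m for m in self.assignment.unique() if m != GREY]


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _correlation(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; constant columns -> 0, logged."""
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant metabolites; "
                      "their correlations are set to 0")
    Xs = (X - X.mean(axis=0)) / np.where(constant, 1.0, sd)
    C = (Xs.T @ Xs) / X.shape[0]
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def adjacency(X: pd.DataFrame, cfg: NetworkConfig | None = None) -> pd.DataFrame:
    """Soft-thresholded correlation adjacency; unit diagonal, entries in [0,1]."""
    cfg = cfg if cfg is not None else NetworkConfig()
    if X.shape[0] < 3:
        raise EmptyInputError("adjacency needs at least 3 samples")
    C = _correlation(X.to_numpy(float))
    if cfg.network_type == "unsigned":
        A = np.abs(C) ** cfg.power
    else:
        A = ((1.0 + C) / 2.0) ** cfg.power
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=X.columns, columns=X.columns)


def tom_similarity(A: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of an adjacency matrix."""
    Av = np.asarray(A, float)
    if not np.allclose(Av, Av.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if not np.allclose(np.diag(Av), 1.0, atol=1e-12):
        raise ValidationError("adjacency diagonal must be 1")
    if Av.min() < -1e-12 or Av.max() > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    A0 = Av.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    L = A0 @ A0                       # L_ij = sum_u a_iu a_uj (u != i, j on offdiag)
    kmin = np.minimum.outer(k, k)
    tom = (L + A0) / (kmin + 1.0 - A0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=A.index, columns=A.columns)


def pick_soft_threshold(X: pd.DataFrame,
                        candidate_powers=tuple(range(1, 13)),
                        target_r2: float = 0.8,
                        network_type: str = "unsigned",
                        n_bins: int = 8) -> int:
    """Smallest power whose connectivity distribution fits a scale-free law.

    For each candidate power the node connectivities ``k_i`` are binned
    (log10 scale, >= 8 bins when possible) and log10 p(k) is regressed on
    log10 k; the fit index is the sign-adjusted R^2 (negated when the slope
    is positive).  The smallest power reaching ``target_r2`` wins; if none
    does, the best-fitting power is returned with a warning.  A nonpositive
    ``target_r2`` is vacuous and returns the smallest candidate.
    """
    candidates = sorted(candidate_powers)
    if len(candidates) < 3:
        raise ParameterError("need at least 3 candidate powers")
    if target_r2 <= 0:
        return candidates[0]
    fits: dict[int, float] = {}
    for beta in candidates:
        cfg = NetworkConfig(power=beta, network_type=network_type)
        A = adjacency(X, cfg).to_numpy()
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        r2 = _scale_free_fit(k, n_bins)
        if np.isnan(r2):
            continue
        fits[beta] = r2
        if r2 >= target_r2:
            return beta
    if not fits:
        warnings.warn("degenerate connectivity distribution; falling back to "
                      "the default power 6")
        return 6 if 6 in candidates else candidates[-1]
    best = max(fits, key=lambda b: (fits[b], -b))
    warnings.warn(f"no candidate power reached scale-free R^2 {target_r2}; "
                  f"using best fit beta={best} (R^2={fits[best]:.3f})")
    return best


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Sign-adjusted R^2 of log10 p(k) against log10 k over connectivity bins."""
    k = k[k > 0]
    if len(np.unique(np.round(k, 12))) < 3:
        return np.nan
    bins = n_bins
    if len(np.unique(k)) < n_bins:
        bins = max(len(np.unique(k)) // 2, 2)
        warnings.warn(f"fewer than {n_bins} distinct connectivities; "
                      f"binning reduced to {bins}")
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return np.nan
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = np.polyval([slope, intercept], xs)
    ss_res = float(np.sum((np.array(ys) - yhat) ** 2))
    ss_tot = float(np.sum((np.array(ys) - np.mean(ys)) ** 2))
    if ss_tot == 0:
        return np.nan
    r2 = 1.0 - ss_res / ss_tot
    return -r2 if slope > 0 else r2


# ---------------------------------------------------------------------------
# module detection and summaries
# ---------------------------------------------------------------------------

def detect_modules(tom: pd.DataFrame,
                   cfg: NetworkConfig | None = None) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` are relabelled grey; surviving
    modules are labelled M1, M2, ... by decreasing size with ties broken by
    the alphabetically first member name.
    """
    cfg = cfg if cfg is not None else NetworkConfig()
    names = list(tom.index)
    D = 1.0 - np.asarray(tom, float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    flat = fcluster(Z, t=cfg.cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for name, c in zip(names, flat):
        clusters.setdefault(int(c), []).append(name)
    keep = [sorted(v) for v in clusters.values() if len(v) >= cfg.min_module_size]
    keep.sort(key=lambda mem: (-len(mem), mem[0]))
    assignment = pd.Series(GREY, index=names, name="module")
    for i, members in enumerate(keep, start=1):
        assignment.loc[members] = f"M{i}"
    if not keep:
        warnings.warn("no module exceeded min_module_size; all metabolites grey")
    return ModuleSet(assignment=assignment)


def module_eigenprofile(X: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized profiles.

    Scaled to unit (sample) variance and oriented so its correlation with
    the module's average standardized profile is positive.  A single-member
    module's eigenprofile is that member's standardized profile itself.
    """
    profiles = {}
    for module in sorted(set(assignment) - {GREY}):
        members = assignment.index[assignment == module]
        sub = X[members].to_numpy(float)
        sd = sub.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = (sub - sub.mean(axis=0)) / sd
        if Z.shape[1] == 1:
            e = Z[:, 0]
        else:
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            e = U[:, 0]
        e_sd = e.std(ddof=1)
        if e_sd > 0:
            e = e / e_sd
        avg = Z.mean(axis=1)
        if float(e @ (avg - avg.mean())) < 0:
            e = -e
        profiles[module] = e
    if not profiles:
        raise EmptyInputError("no non-grey modules to summarize")
    return pd.DataFrame(profiles, index=X.index).T


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided Student-t p-value of a Pearson correlation (n-2 df)."""
    if n < 3:
        raise ParameterError("need n >= 3 for a correlation test")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return float(np.nextafter(0, 1))  # underflow guard
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * t_dist.sf(abs(t), n - 2)
    return float(max(p, np.nextafter(0, 1)))


def treatment_indicators(conditions: pd.Series) -> pd.DataFrame:
    """Binary per-treatment indicator traits (1 = sample under the treatment)."""
    return pd.get_dummies(conditions).astype(float).sort_index(axis=1)


def module_trait_correlation(eigenprofiles: pd.DataFrame,
                             traits: pd.DataFrame,
                             cfg: NetworkConfig | None = None) -> pd.DataFrame:
    """Pearson r and Student-t p of each eigenprofile against each trait.

    Adds a ``selected`` flag: r > r_cut and p < p_cut (both strict).
    Constant traits are excluded with a warning.
    """
    cfg = cfg if cfg is not None else NetworkConfig()
    n = eigenprofiles.shape[1]
    if n < 3:
        raise EmptyInputError("need at least 3 samples for trait correlation")
    rows = []
    for trait in traits.columns:
        tv = traits[trait].to_numpy(float)
        if tv.std() == 0:
            warnings.warn(f"trait '{trait}' is constant; excluded")
            continue
        for module in eigenprofiles.index:
            e = eigenprofiles.loc[module].to_numpy(float)
            r = float(np.corrcoef(e, tv)[0, 1])
            p = corr_pvalue(r, n)
            rows.append({"module": module, "trait": trait, "r": r, "p": p,
                         "selected": bool(r > cfg.r_cut and p < cfg.p_cut)})
    return pd.DataFrame(rows)


def build_modules(X: pd.DataFrame, conditions: pd.Series,
                  cfg: NetworkConfig | None = None,
                  extra_traits: pd.DataFrame | None = None) -> ModuleSet:
    """End-to-end module stage: adjacency -> TOM -> modules -> trait table."""
    cfg = cfg if cfg is not None else NetworkConfig()
    A = adjacency(X, cfg)
    tom = tom_similarity(A)
    ms = detect_modules(tom, cfg)
    if not ms.module_labels():
        return ms
    ms.eigenprofiles = module_eigenprofile(X, ms.assignment)
    traits = treatment_indicators(conditions)
    if extra_traits is not None:
        traits = pd.concat([traits, extra_traits], axis=1)
    ms.trait_correlation = module_trait_correlation(ms.eigenprofiles, traits, cfg)
    picked = ms.trait_correlation[ms.trait_correlation["selected"]]
    # a module's reported treatment = its strongest selected association
    for module, grp in picked.groupby("module"):
        best = grp.sort_values("r", ascending=False).iloc[0]
        ms.selected[str(module)] = str(best["trait"])
    return ms
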