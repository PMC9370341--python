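"""Flavor-compound quantification and odor-activity screening.

Implements the GC-MS bookkeeping used to call a volatile compound
*characteristic* of a fermented-food sample series:

* Kovats retention index against bracketing n-alkanes,
    RI = 100 n + 100 (t_i - t_n) / (t_{n+1} - t_n)
* internal-standard semi-quantification,
    C = unit_factor * A_x C_0 V / (A_0 m)
* odor activity value with C in µg/100 g and T in µg/g,
    OAV = C / (100 T)

A compound is characteristic when its maximum OAV across samples
reaches 1 (inclusive boundary). The printed form of the OAV equation in
the source study ("OAV = CT x 100") is dimensionally inconsistent;
C/(100 T) is the only reading under which every compound of the
published table passes its own screen, and it is the only form
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FlavorTable, ValidationError

__all__ = [
    "RIInput",
    "QuantInput",
    "OAVResult",
    "retention_index",
    "quantify",
    "oav",
    "screen_characteristic",
    "class_tally",
    "flavor_pca",
]


@dataclass(frozen=True)
class RIInput:
    """Bracketing-alkane description of one GC peak.

    n: carbon number of the alkane eluting before the compound (7..40);
    t_n, t_n1: retention times (min) of alkanes n and n+1;
    t_i: retention time (min) of the compound, t_n < t_i < t_n1.
    """

    n: int
    t_n: float
    t_n1: float
    t_i: float

    def __post_init__(self) -> None:
        if not 7 <= self.n <= 40:
            raise ValidationError(f"alkane carbon number must be in 7..40, got {self.n}")
        if not self.t_n1 > self.t_n:
            raise ValidationError("alkane retention times must satisfy t_n1 > t_n")
        if not self.t_n < self.t_i < self.t_n1:
            raise ValidationError(
                f"compound retention time {self.t_i} outside ({self.t_n}, {self.t_n1})"
            )


@dataclass(frozen=True)
class QuantInput:
    """Peak areas and internal-standard bookkeeping for one analyte.

    A_x, A_0: peak areas of analyte and internal standard (> 0);
    C_0: internal-standard concentration (mg/L); V: spiked volume (µL);
    m: sample mass (g).
    """

    A_x: float
    A_0: float
    C_0: float
    V: float
    m: float

    def __post_init__(self) -> None:
        for name in ("A_x", "A_0", "C_0", "V", "m"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v!r}")


@dataclass
class OAVResult:
    """Per-compound screening outcome: per-sample OAVs and the verdict."""

    name: str
    oavs: pd.Series  # index: sample labels
    max_oav: float
    is_characteristic: bool


def retention_index(x: RIInput) -> float:
    """Kovats retention index; strictly between 100 n and 100 (n+1)."""
    return 100.0 * x.n + 100.0 * (x.t_i - x.t_n) / (x.t_n1 - x.t_n)


#: mg/L * µL / g  ==  ng/g  ==  0.1 µg/100 g
DEFAULT_UNIT_FACTOR = 0.1


def quantify(x: QuantInput, unit_factor: float = DEFAULT_UNIT_FACTOR) -> float:
    """Internal-standard concentration estimate, in µg/100 g by default.

    ``unit_factor`` converts the raw ratio A_x·C_0·V/(A_0·m) into the
    output unit; the default 0.1 maps (mg/L, µL, g) onto µg/100 g. The
    factor is exposed rather than hard-coded because the published unit
    chain is internally inconsistent.
    """
    if not unit_factor > 0:
        raise ValidationError(f"unit_factor must be > 0, got {unit_factor}")
    return unit_factor * x.A_x * x.C_0 * x.V / (x.A_0 * x.m)


def oav(c: float, t: float) -> float:
    """Odor activity value: C (µg/100 g) over threshold T (µg/g).

    Missing concentrations should be passed as 0 (not detected means no
    odor contribution).
    """
    if not (np.isfinite(t) and t > 0):
        raise ValidationError(f"threshold must be > 0, got {t!r}")
    if c < 0:
        raise ValidationError(f"concentration must be >= 0, got {c!r}")
    return c / (100.0 * t)


def screen_characteristic(
    ft: FlavorTable, missing_as_zero: bool = True
) -> list[OAVResult]:
    """Screen every compound of ``ft``; characteristic iff max OAV >= 1.

    Output preserves the input compound order; per-sample OAVs are kept
    so the timepoint at which a compound becomes flavor-active can be
    inspected.
    """
    conc = ft.concentrations(missing_as_zero=missing_as_zero)
    thr = ft.thresholds()
    results = []
    for rec in ft.compounds:
        row = conc.loc[rec.name]
        oavs = row / (100.0 * rec.threshold)
        oavs.name = rec.name
        mx = float(np.nanmax(oavs.to_numpy())) if len(oavs) else 0.0
        if not np.isfinite(mx):
            mx = 0.0
        results.append(
            OAVResult(
                name=rec.name,
                oavs=oavs,
                max_oav=mx,
                is_characteristic=bool(mx >= 1.0),
            )
        )
    return results


def class_tally(results: list[OAVResult], ft: FlavorTable) -> dict[str, int]:
    """Count characteristic compounds per chemical class.

    The counts partition the characteristic set: their sum equals the
    number of characteristic compounds.
    """
    if [r.name for r in results] != ft.names:
        raise ValidationError("results are not aligned with the flavor table")
    tally = {cls: 0 for cls in sorted({c.chem_class for c in ft.compounds})}
    for rec, res in zip(ft.compounds, results):
        if res.is_characteristic:
            tally[rec.chem_class] += 1
    return tally


def characteristic_table(ft: FlavorTable) -> pd.DataFrame:
    """Tidy screening summary: class, per-sample OAV, max OAV, verdict."""
    results = screen_characteristic(ft)
    rows = {}
    for rec, res in zip(ft.compounds, results):
        rows[rec.name] = {
            "chem_class": rec.chem_class,
            **{f"oav_{s}": res.oavs[s] for s in ft.samples},
            "max_oav": res.max_oav,
            "characteristic": res.is_characteristic,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "compound"
    return out


def flavor_pca(ft: FlavorTable, scaling: str = "unit_variance"):
    """Exploratory PCA of the flavor profile (samples as observations).

    ``scaling="unit_variance"`` autoscales each compound (constant
    compounds are dropped first); ``"center_only"`` mean-centers without
    scaling. Missing concentrations are treated as 0. Returns
    ``(scores, loadings, explained)`` where ``scores @ loadings.T``
    reconstructs the preprocessed matrix and ``explained`` holds the
    non-increasing explained-variance fractions.
    """
    if scaling not in ("unit_variance", "center_only"):
        raise ValidationError(f"unknown scaling {scaling!r}")
    X = ft.concentrations(missing_as_zero=True).T  # samples x compounds
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    kept = list(X.columns)
    if scaling == "unit_variance":
        sd = X.std(axis=0, ddof=0)
        kept = list(X.columns[sd > 0])
        X = X[kept]
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    else:
        X = X - X.mean(axis=0)

    from sklearn.decomposition import PCA

    n_comp = min(X.shape[0] - 1, X.shape[1])
    if n_comp < 1:
        raise ValidationError("PCA needs at least one non-constant compound")
    pca = PCA(n_components=n_comp, svd_solver="full")
    with np.errstate(invalid="ignore"):  # 0/0 ratio on an all-constant matrix
        scores = pca.fit_transform(X.to_numpy())
    total_var = X.to_numpy().var(axis=0, ddof=1).sum()
    if total_var > 0:
        explained = pca.explained_variance_ / total_var
    else:  # identical samples: every nontrivial component explains nothing
        explained = np.zeros(n_comp)
    scores = pd.DataFrame(
        scores, index=X.index, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    loadings = pd.DataFrame(
        pca.components_.T, index=kept, columns=scores.columns
    )
    return scores, loadings, explained
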