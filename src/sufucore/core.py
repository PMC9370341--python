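"""Three-criterion core-microbiota selection.

A genus is *core* for a fermentation stage when it simultaneously

1. is dominant (stage-mean relative abundance > 1%),
2. is strongly flavor-associated (qualifying-compound count above the
   stage's threshold in the genus-flavor screen), and
3. has co-occurrence degree above the degree threshold (default
   strictly greater than 4).

The report keeps the full evidence trail (mean abundance, qualifying
compounds with signs, degree) for every dominant genus, so the reader
can see why each genus was kept or dropped — including the correlation
signs needed to apply a promoter-only (positive-association) reading.

For reference, the source study names five early-stage core genera
(Pseudomonas, Tetragenococcus, Lysinibacillus, Pantoea,
Burkholderia-Caballeronia-Paraburkholderia) and three late-stage ones
(Exiguobacterium, Bacillus, Pseudomonas); those sets depend on raw
sequencing data that this package does not consume, so they are
documented expected outputs, not computable checks (see
:mod:`sufucore.reference`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import StageRule, assign_stages, dominant_genera, to_relative
from .networks import (
    FlavorScreenResult,
    Network,
    ScreeningCriteria,
    cooccurrence_network,
    genus_flavor_screen,
)
from .tables import AbundanceTable, FlavorTable, ValidationError

__all__ = ["CoreReport", "screen_core", "run_stagewise", "replicate_flavor_means"]

SCHEMA_VERSION = 1


@dataclass
class CoreReport:
    """Evidence-backed core set for one stage."""

    stage: str
    dominant_set: list[str]
    flavor_set: list[str]
    qualifying_counts: dict[str, int]
    network_set: list[str]  # genera passing the degree rule
    degrees: dict[str, int]
    core_set: list[str]  # ordered by descending degree, then name
    evidence: pd.DataFrame  # one row per dominant genus
    empty_stage: bool = False

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "stage": self.stage,
            "empty_stage": self.empty_stage,
            "dominant_set": self.dominant_set,
            "flavor_set": self.flavor_set,
            "qualifying_counts": self.qualifying_counts,
            "network_set": self.network_set,
            "degrees": self.degrees,
            "core_set": self.core_set,
            "evidence": self.evidence.reset_index().to_dict(orient="records"),
        }

    @classmethod
    def empty(cls, stage: str) -> "CoreReport":
        return cls(
            stage=stage,
            dominant_set=[],
            flavor_set=[],
            qualifying_counts={},
            network_set=[],
            degrees={},
            core_set=[],
            evidence=pd.DataFrame(
                columns=["mean_abundance", "qualifying_compounds", "degree", "is_core"]
            ).rename_axis("genus"),
            empty_stage=True,
        )


def screen_core(
    dominant: list[str],
    flavor_screened: FlavorScreenResult,
    net: Network,
    crit: ScreeningCriteria = ScreeningCriteria(),
    mean_abundance: dict[str, float] | None = None,
) -> CoreReport:
    """Intersect the three criteria into a core set with evidence rows.

    The three inputs must describe the same stage: the network nodes and
    the screened genera must come from the dominant set.
    """
    stage = flavor_screened.stage
    if set(net.nodes) - set(dominant):
        raise ValidationError("network contains nodes outside the dominant set")
    if set(flavor_screened.associations) - set(dominant):
        raise ValidationError("flavor screen contains genera outside the dominant set")

    flavor_set = [g for g in flavor_screened.passing if g in dominant]
    network_set = [g for g in net.nodes if crit.degree_passes(net.degrees[g])]
    core = [g for g in dominant if g in set(flavor_set) and g in set(network_set)]
    core.sort(key=lambda g: (-net.degrees.get(g, 0), g))

    rows = {}
    for g in dominant:
        rows[g] = {
            "mean_abundance": (mean_abundance or {}).get(g, np.nan),
            "qualifying_compounds": flavor_screened.qualifying_counts.get(g, 0),
            "degree": net.degrees.get(g, 0),
            "is_core": g in set(core),
        }
    evidence = pd.DataFrame.from_dict(rows, orient="index").rename_axis("genus")
    return CoreReport(
        stage=stage,
        dominant_set=list(dominant),
        flavor_set=flavor_set,
        qualifying_counts=dict(flavor_screened.qualifying_counts),
        network_set=network_set,
        degrees=dict(net.degrees),
        core_set=core,
        evidence=evidence,
    )


def replicate_flavor_means(
    flavor: pd.DataFrame, at: AbundanceTable, day_prefix: str = "d"
) -> pd.DataFrame:
    """Expand a compounds x timepoint-mean matrix onto replicate samples.

    When flavor data exist only as per-timepoint means (as in the
    published table), each mean column d<day> is copied to every
    replicate sample of that day. Correlations computed this way use
    repeated values and effectively n = number of timepoints; a warning
    is emitted because replicate-level flavor variation is unavailable.
    """
    cols = {}
    for m in at.meta:
        label = f"{day_prefix}{m.day}"
        if label not in flavor.columns:
            raise ValidationError(
                f"flavor matrix has no column {label!r} for sample {m.sample_id!r}"
            )
        cols[m.sample_id] = flavor[label]
    warnings.warn(
        "flavor timepoint means were replicated across within-day replicates; "
        "correlations effectively use n = number of timepoints",
        UserWarning,
        stacklevel=2,
    )
    return pd.DataFrame(cols)


def _stage_report(
    rel: AbundanceTable,
    flavor: pd.DataFrame,
    crit: ScreeningCriteria,
    stage: str,
) -> CoreReport:
    stage_at = rel.restrict(stage)
    dominant = dominant_genera(rel, stage, threshold=crit.abundance_min)
    if len(dominant) < 2:
        return CoreReport.empty(stage)
    dom_values = stage_at.values[dominant]
    stage_flavor = flavor[stage_at.sample_ids]
    screened = genus_flavor_screen(dom_values, stage_flavor, crit, stage)
    net = cooccurrence_network(stage_at, dominant, crit)
    means = stage_at.values[dominant].mean(axis=0).to_dict()
    return screen_core(dominant, screened, net, crit, mean_abundance=means)


def run_stagewise(
    at: AbundanceTable,
    flavor: pd.DataFrame | FlavorTable,
    crit: ScreeningCriteria = ScreeningCriteria(),
    rule: StageRule = StageRule(),
    characteristic_only: bool = True,
) -> dict[str, CoreReport]:
    """Run dominance -> flavor screen -> co-occurrence -> intersection
    independently for the early and late stages.

    ``flavor`` is either a compounds x samples matrix whose columns
    match the abundance sample ids, or a :class:`FlavorTable` carrying
    timepoint means (then expanded over replicates with a warning). By
    default the flavor matrix is first reduced to characteristic
    compounds (max OAV >= 1), mirroring the study's screen.

    A stage with no samples (or fewer than two dominant genera) yields
    an explicit empty report rather than an error.
    """
    if at.mode == "counts":
        rel = to_relative(at)
    else:
        rel = at
    if any(m.stage is None for m in rel.meta):
        rel = assign_stages(rel, rule)

    if isinstance(flavor, FlavorTable):
        ft = flavor
        if characteristic_only:
            from .flavor import screen_characteristic

            res = screen_characteristic(ft)
            ft = ft.subset([r.name for r in res if r.is_characteristic])
        matrix = ft.concentrations(missing_as_zero=True)
        if list(matrix.columns) != rel.sample_ids:
            matrix = replicate_flavor_means(matrix, rel)
    else:
        matrix = flavor
        missing = [s for s in rel.sample_ids if s not in matrix.columns]
        if missing:
            raise ValidationError(f"flavor matrix lacks sample columns: {missing}")

    reports = {}
    for stage in ("early", "late"):
        if not any(m.stage == stage for m in rel.meta):
            reports[stage] = CoreReport.empty(stage)
            continue
        reports[stage] = _stage_report(rel, matrix, crit, stage)
    return reports
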