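"""Tabular containers and I/O for the screening pipeline.

Three kinds of input tables are handled:

* a flavor-compound table (compounds x timepoints, concentrations in
  µg/100 g, plus per-compound odor detection thresholds in µg/g),
* a genus-level abundance table (samples x genera, raw counts or
  relative abundances, with per-sample day/replicate metadata),
* a physicochemical table (samples x {total acidity, salt, moisture,
  ethanol}).

A transcription of the published sufu flavor table (41 compounds over
seven post-fermentation timepoints, d0..d130) ships as package data and
is returned by :func:`load_table1_fixture`.

Cells printed as "−" (either U+2212 or an ASCII hyphen) or left empty
mean *not detected*; they are stored as missing (NaN) and are therefore
distinguishable from a measured zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CHEM_CLASSES",
    "MISSING_TOKENS",
    "CompoundRecord",
    "FlavorTable",
    "SampleMeta",
    "AbundanceTable",
    "PhysicoTable",
    "read_flavor_table",
    "load_table1_fixture",
    "read_abundance_table",
    "read_physico_table",
    "write_network",
    "read_network",
    "write_report",
]

CHEM_CLASSES = (
    "ester",
    "alcohol",
    "aldehyde",
    "ketone",
    "phenol",
    "acid",
    "furan",
    "pyrazine",
)

#: Tokens that parse as "compound not detected".
MISSING_TOKENS = {"−", "-", "", "nan", "NA"}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class CompoundRecord:
    """One volatile compound: name, chemical class, odor threshold (µg/g)."""

    name: str
    chem_class: str
    threshold: float
    odor: str = ""

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValidationError(
                f"compound {self.name!r}: unknown chem_class {self.chem_class!r}; "
                f"expected one of {CHEM_CLASSES}"
            )
        if not np.isfinite(self.threshold) or self.threshold <= 0:
            raise ValidationError(
                f"compound {self.name!r}: threshold must be > 0, got {self.threshold!r}"
            )


@dataclass
class FlavorTable:
    """Compounds x samples concentration matrix with per-compound metadata.

    ``values`` is a DataFrame indexed by compound name with one column per
    sample (timepoint or replicate label); NaN encodes *not detected*.
    ``sds`` optionally carries matching standard deviations.
    """

    compounds: list[CompoundRecord]
    values: pd.DataFrame
    sds: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate compound names: {dupes}")
        if list(self.values.index) != names:
            raise ValidationError("values index must equal the compound name list")
        arr = self.values.to_numpy(dtype=float)
        if (arr[np.isfinite(arr)] < 0).any():
            raise ValidationError("concentrations must be >= 0 where present")
        if self.sds is not None and self.sds.shape != self.values.shape:
            raise ValidationError("sds matrix must match values in shape")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def record(self, name: str) -> CompoundRecord:
        for c in self.compounds:
            if c.name == name:
                return c
        raise KeyError(name)

    def thresholds(self) -> pd.Series:
        return pd.Series(
            [c.threshold for c in self.compounds], index=self.names, name="threshold"
        )

    def concentrations(self, missing_as_zero: bool = True) -> pd.DataFrame:
        """Concentration matrix; by default not-detected cells become 0.0."""
        if missing_as_zero:
            return self.values.fillna(0.0)
        return self.values.copy()

    def subset(self, names: Sequence[str]) -> "FlavorTable":
        keep = [c for c in self.compounds if c.name in set(names)]
        return FlavorTable(
            compounds=keep,
            values=self.values.loc[[c.name for c in keep]],
            sds=None if self.sds is None else self.sds.loc[[c.name for c in keep]],
        )


@dataclass
class SampleMeta:
    sample_id: str
    day: int
    replicate: int
    stage: str | None = None  # "start" | "early" | "late", set by assign_stages

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError(f"sample {self.sample_id}: day must be >= 0")
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id}: replicate must be >= 1")


@dataclass
class AbundanceTable:
    """Samples x genera matrix, either raw counts or relative abundances.

    ``values`` is indexed by sample_id; ``mode`` is ``"counts"`` or
    ``"relative"``. Relative rows must sum to 1 (tolerance 1e-6 on read,
    exact to 1e-9 when produced by :func:`sufucore.community.to_relative`).
    """

    meta: list[SampleMeta]
    values: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        ids = [m.sample_id for m in self.meta]
        if list(self.values.index) != ids:
            raise ValidationError("values index must equal the sample_id list")
        pairs = [(m.day, m.replicate) for m in self.meta]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (day, replicate) pairs in sample metadata")
        genera = list(self.values.columns)
        if len(set(genera)) != len(genera):
            raise ValidationError("genus names must be unique")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("abundance matrix must not contain missing values")
        if (arr < 0).any():
            bad = self.values.index[(arr < 0).any(axis=1)][0]
            raise ValidationError(f"negative abundance in sample {bad!r}")
        if self.mode == "relative":
            sums = arr.sum(axis=1)
            off = np.abs(sums - 1.0) > 1e-6
            if off.any():
                bad = self.values.index[off][0]
                raise ValidationError(
                    f"relative abundances of sample {bad!r} sum to "
                    f"{sums[off][0]:.6g}, expected 1"
                )

    @property
    def genera(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": [m.day for m in self.meta],
                "replicate": [m.replicate for m in self.meta],
                "stage": [m.stage for m in self.meta],
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def restrict(self, stage: str) -> "AbundanceTable":
        """Sub-table containing only samples assigned to ``stage``."""
        keep = [m for m in self.meta if m.stage == stage]
        if not keep:
            raise ValidationError(f"no samples assigned to stage {stage!r}")
        ids = [m.sample_id for m in keep]
        return AbundanceTable(
            meta=[SampleMeta(m.sample_id, m.day, m.replicate, m.stage) for m in keep],
            values=self.values.loc[ids].copy(),
            mode=self.mode,
        )


DEFAULT_FACTORS = ("total_acidity", "salt", "moisture", "ethanol")


@dataclass
class PhysicoTable:
    """Samples x physicochemical factors (no missing cells allowed)."""

    values: pd.DataFrame  # index sample_id, columns factor names

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("physicochemical table must not contain missing cells")

    @property
    def factors(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def restrict(self, sample_ids: Iterable[str]) -> "PhysicoTable":
        return PhysicoTable(values=self.values.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# readers


def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect in ("\t", "tab"):
        return "\t"
    if dialect in (",", "comma"):
        return ","
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _parse_cell(raw: object, row: str, col: str) -> float:
    txt = str(raw).strip()
    if txt in MISSING_TOKENS or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    try:
        return float(txt.replace("−", "-"))
    except ValueError:
        raise ValidationError(
            f"non-numeric cell at row {row!r}, column {col!r}: {raw!r}"
        ) from None


def read_flavor_table(path: str | Path, dialect: str | None = None) -> FlavorTable:
    """Read a flavor-compound table.

    Expected columns: ``compound``, ``chem_class``, ``threshold``,
    optionally ``odor``, then one column per sample. "−" or empty cells
    mean not detected.
    """
    path = Path(path)
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    required = {"compound", "chem_class", "threshold"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"flavor table header must contain {sorted(required)}; got {list(df.columns)}"
        )
    meta_cols = ["compound", "chem_class", "threshold"] + (
        ["odor"] if "odor" in df.columns else []
    )
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ValidationError("flavor table has no sample columns")

    compounds: list[CompoundRecord] = []
    rows = []
    for i, rec in df.iterrows():
        name = rec["compound"].strip()
        thr_raw = rec["threshold"]
        try:
            thr = float(thr_raw)
        except ValueError:
            raise ValidationError(
                f"row {i + 1} ({name!r}): non-numeric threshold {thr_raw!r}"
            ) from None
        if thr <= 0:
            raise ValidationError(f"row {i + 1} ({name!r}): non-positive threshold {thr}")
        compounds.append(
            CompoundRecord(
                name=name,
                chem_class=rec["chem_class"].strip(),
                threshold=thr,
                odor=rec.get("odor", "").strip() if "odor" in df.columns else "",
            )
        )
        rows.append([_parse_cell(rec[c], name, c) for c in sample_cols])

    values = pd.DataFrame(rows, index=[c.name for c in compounds], columns=sample_cols)
    return FlavorTable(compounds=compounds, values=values)


def load_table1_fixture() -> FlavorTable:
    """The bundled 41-compound x 7-timepoint sufu flavor table (mean values)."""
    with resources.as_file(
        resources.files("sufucore").joinpath("data/table1.tsv")
    ) as p:
        return read_flavor_table(p, dialect="tab")


def read_abundance_table(path: str | Path, mode: str = "auto") -> AbundanceTable:
    """Read a samples x genera table with ``sample_id``, ``day``, ``replicate``
    metadata columns. ``mode`` is ``"auto"`` (detect counts vs relative),
    ``"counts"`` or ``"relative"``."""
    path = Path(path)
    sep = _sniff_delimiter(path, None)
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    required = {"sample_id", "day", "replicate"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"abundance table header must contain {sorted(required)}"
        )
    genus_cols = [c for c in df.columns if c not in required]
    meta = [
        SampleMeta(str(r.sample_id), int(r.day), int(r.replicate))
        for r in df.itertuples()
    ]
    values = df[genus_cols].astype(float)
    values.index = pd.Index([m.sample_id for m in meta], name="sample_id")

    arr = values.to_numpy()
    if (arr < 0).any():
        bad = values.index[(arr < 0).any(axis=1)][0]
        raise ValidationError(f"negative abundance in sample {bad!r}")
    sums = arr.sum(axis=1)
    if mode == "auto":
        if np.allclose(sums, 1.0, atol=1e-6):
            mode = "relative"
        elif np.allclose(arr, np.round(arr)):
            mode = "counts"
        else:
            raise ValidationError(
                "cannot auto-detect mode: rows neither sum to 1 nor look like counts"
            )
    if mode == "relative" and not np.allclose(sums, 1.0, atol=1e-6):
        bad = values.index[np.abs(sums - 1.0) > 1e-6][0]
        raise ValidationError(
            f"relative abundances of sample {bad!r} do not sum to 1"
        )
    return AbundanceTable(meta=meta, values=values, mode=mode)


def read_physico_table(path: str | Path) -> PhysicoTable:
    path = Path(path)
    sep = _sniff_delimiter(path, None)
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    if "sample_id" not in df.columns:
        raise ValidationError("physicochemical table must have a sample_id column")
    df = df.set_index("sample_id")
    return PhysicoTable(values=df.astype(float))


# ---------------------------------------------------------------------------
# network / report serialization


def write_network(net, path: str | Path, format: str = "edge_list_tsv") -> None:
    """Serialize a co-occurrence / association network.

    ``edge_list_tsv`` writes source/target/rho/p/sign rows (plus a node
    list comment header so isolated nodes survive the round trip);
    ``graphml`` goes through networkx.
    """
    import networkx as nx

    path = Path(path)
    if format == "edge_list_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# nodes: " + ",".join(net.nodes) + "\n")
            fh.write("source\ttarget\trho\tp\tsign\n")
            for e in net.edges:
                fh.write(
                    f"{e.source}\t{e.target}\t{e.rho!r}\t{e.p!r}\t{e.sign}\n"
                )
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge_list_tsv"):
    """Inverse of :func:`write_network` (lossless for nodes, edges, rho/p)."""
    from .networks import Edge, Network

    path = Path(path)
    if format == "edge_list_tsv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip()
            nodes = header.removeprefix("# nodes:").strip()
            node_list = [n for n in nodes.split(",") if n]
            fh.readline()  # column header
            edges = []
            for line in fh:
                if not line.strip():
                    continue
                s, t, rho, p, sign = line.rstrip("\n").split("\t")
                edges.append(Edge(s, t, float(rho), float(p), sign))
        return Network.from_edges(node_list, edges)
    if format == "graphml":
        import networkx as nx
        from .networks import Edge, Network

        g = nx.read_graphml(path)
        edges = [
            Edge(u, v, float(d["rho"]), float(d["p"]), d["sign"])
            for u, v, d in g.edges(data=True)
        ]
        return Network.from_edges(list(g.nodes), edges)
    raise ValidationError(f"unknown network format {format!r}")


def write_report(report, path: str | Path) -> None:
    """Write a core-microbiota report (or any to_dict-able object) as JSON."""
    path = Path(path)
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
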