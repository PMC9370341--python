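"""End-to-end pipeline runs from a single configuration.

``run(RunConfig)`` executes the whole inference chain — OAV screen,
alpha diversity (counts inputs), stage partition, dominance, genus-
flavor screening, co-occurrence networks, core-set intersection and
constrained ordination — and writes every artifact (TSV tables, edge
lists, JSON reports, a run log) into an output directory. The same
config and seed always reproduce byte-identical reports; the config
hash is recorded in the report header.

Inputs are either file paths, the bundled flavor fixture
(``fixture:table1``) or the synthetic generator (``synthetic:default``,
``synthetic:null``). Every screening threshold is a parameter with the
study's value as its default; deviations from the defaults are listed
in a banner in the run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, core, flavor, ordination, synth, tables
from .networks import ScreeningCriteria
from .tables import ValidationError

__all__ = ["RunConfig", "run", "load_config"]

log = logging.getLogger("sufucore")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``flavor_input`` / ``abundance_input`` / ``physico_input`` are file
    paths, or ``fixture:table1`` (flavor only), or ``synthetic:default``
    / ``synthetic:null`` to generate all three tables internally.
    """

    outdir: str = "sufucore_out"
    flavor_input: str | None = "fixture:table1"
    abundance_input: str | None = None
    physico_input: str | None = None
    criteria: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    stage_rule: community.StageRule = field(default_factory=community.StageRule)
    ordination_method: dict = field(
        default_factory=lambda: {"early": "rda", "late": "cca"}
    )
    seed: int = 0
    log_level: str = "INFO"
    flavor_only: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("run config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "criteria" in kwargs:
        kwargs["criteria"] = ScreeningCriteria(**kwargs["criteria"])
    if "stage_rule" in kwargs:
        sr = {k: frozenset(v) for k, v in kwargs["stage_rule"].items()}
        kwargs["stage_rule"] = community.StageRule(**sr)
    return RunConfig(**kwargs)


def _resolve_inputs(cfg: RunConfig):
    """Load or generate (flavor, abundance, physico, truth-or-None)."""
    synth_mode = None
    for src in (cfg.flavor_input, cfg.abundance_input):
        if src and src.startswith("synthetic:"):
            synth_mode = src.split(":", 1)[1]
    if synth_mode is not None:
        if synth_mode == "default":
            scfg = synth.SynthConfig(seed=cfg.seed)
        elif synth_mode == "null":
            scfg = synth.SynthConfig.null(seed=cfg.seed)
        else:
            raise ValidationError(f"unknown synthetic preset {synth_mode!r}")
        at, ft, ph, truth = synth.generate(scfg)
        return ft, at, ph, truth

    if cfg.flavor_input == "fixture:table1":
        ft = tables.load_table1_fixture()
    elif cfg.flavor_input:
        p = Path(cfg.flavor_input)
        if not p.exists():
            raise ValidationError(f"flavor input not found: {p}")
        ft = tables.read_flavor_table(p)
    else:
        ft = None

    at = None
    if cfg.abundance_input:
        p = Path(cfg.abundance_input)
        if not p.exists():
            raise ValidationError(f"abundance input not found: {p}")
        at = tables.read_abundance_table(p)
    ph = None
    if cfg.physico_input:
        p = Path(cfg.physico_input)
        if not p.exists():
            raise ValidationError(f"physicochemical input not found: {p}")
        ph = tables.read_physico_table(p)
    return ft, at, ph, None


def _banner(cfg: RunConfig) -> list[str]:
    """List deviations of the screening setup from the study defaults."""
    default = ScreeningCriteria()
    lines = []
    for f in dataclasses.fields(ScreeningCriteria):
        got = getattr(cfg.criteria, f.name)
        ref = getattr(default, f.name)
        if got != ref:
            lines.append(f"non-default criterion {f.name}: {got!r} (default {ref!r})")
    return lines


def run(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns a manifest of written artifacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.setLevel(cfg.log_level)
    log.addHandler(handler)
    manifest: dict = {"config_hash": cfg.config_hash(), "artifacts": {}}

    try:
        log.info("run config hash %s", cfg.config_hash())
        for line in _banner(cfg):
            log.warning(line)

        ft, at, ph, truth = _resolve_inputs(cfg)

        if ft is not None:
            oav_table = flavor.characteristic_table(ft)
            path = outdir / "oav.tsv"
            oav_table.to_csv(path, sep="\t")
            manifest["artifacts"]["oav"] = str(path)
            log.info(
                "flavor screen: %d/%d characteristic compounds",
                int(oav_table["characteristic"].sum()),
                len(oav_table),
            )

        if cfg.flavor_only or at is None:
            manifest["flavor_only"] = True
            return manifest

        if at.mode == "counts":
            alpha = community.alpha_diversity(at)
            path = outdir / "alpha.tsv"
            alpha.to_csv(path, sep="\t")
            manifest["artifacts"]["alpha"] = str(path)

        reports = core.run_stagewise(
            at, ft, crit=cfg.criteria, rule=cfg.stage_rule
        )
        rel = community.to_relative(at) if at.mode == "counts" else at
        rel = community.assign_stages(rel, cfg.stage_rule)
        for stage, rep in reports.items():
            path = outdir / f"core_{stage}.json"
            tables.write_report(rep, path)
            manifest["artifacts"][f"core_{stage}"] = str(path)
            ev_path = outdir / f"evidence_{stage}.tsv"
            rep.evidence.to_csv(ev_path, sep="\t")
            manifest["artifacts"][f"evidence_{stage}"] = str(ev_path)
            log.info("%s core set: %s", stage, rep.core_set)
            if not rep.empty_stage and len(rep.dominant_set) >= 2:
                from .networks import cooccurrence_network

                net = cooccurrence_network(
                    rel.restrict(stage), rep.dominant_set, cfg.criteria
                )
                npath = outdir / f"network_{stage}.tsv"
                tables.write_network(net, npath, format="edge_list_tsv")
                gpath = outdir / f"network_{stage}.graphml"
                tables.write_network(net, gpath, format="graphml")
                manifest["artifacts"][f"network_{stage}"] = str(npath)

        if ph is not None:
            ords = {}
            for stage, method in cfg.ordination_method.items():
                if not any(m.stage == stage for m in rel.meta):
                    continue
                sub = rel.restrict(stage)
                env = ph.restrict(sub.sample_ids)
                fn = ordination.rda if method == "rda" else ordination.cca
                res = fn(sub.values, env)
                ords[stage] = {
                    "method": res.method,
                    "constrained_fraction": res.constrained_fraction,
                    "eigenvalues": list(map(float, res.eigenvalues)),
                    "dropped_factors": res.dropped_factors,
                }
                log.info(
                    "%s %s constrained fraction %.4f",
                    stage, method, res.constrained_fraction,
                )
            path = outdir / "ordination.json"
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(ords, fh, indent=2, sort_keys=True)
                fh.write("\n")
            manifest["artifacts"]["ordination"] = str(path)

        if truth is not None:
            recov = synth.evaluate_recovery(reports, truth)
            path = outdir / "recovery.json"
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(recov, fh, indent=2, sort_keys=True)
                fh.write("\n")
            manifest["artifacts"]["recovery"] = str(path)
            log.info("recovery: %s", recov)

        mpath = outdir / "manifest.json"
        with open(mpath, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
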