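"""End-to-end orchestration: delimit, project, classify, date, report.

The report is a plain JSON-serializable dict; all counts it contains are
recomputable from the per-divergence table it carries.  Stages can also be
run standalone through the CLI on intermediate files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import congruence as cg
from . import chronology as ch
from . import geography as geo
from .delimitation import (
    DelimitationConfig,
    auto_min_branch_length,
    delimit_search,
)
from .treeio import parse_newick, parse_nexus_trees, resolve_polytomies

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "intervals_only_mode"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    ml_tree: str
    dated_tree: str
    posterior: str
    samples: str
    rivers: str
    scope: str | None = None
    mode: str = "multi"
    min_branch_length: float = 0.0
    minbr_auto_sites: int | None = None
    outgroup: list[str] = field(default_factory=list)
    restarts: int = 8
    lrt_alpha: float | None = 0.001
    hpd_level: float = 0.95
    burnin_fraction: float = 0.0
    temporal_rule: str = "not-postdate"
    min_determinate_per_side: int = 1
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dict (JSON-serializable)."""
    for name in ("ml_tree", "dated_tree", "posterior", "samples", "rivers"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise PipelineError("inputs", f"{name} file not found: {p}")
    inputs = {
        name: _sha256(getattr(config, name))
        for name in ("ml_tree", "dated_tree", "posterior", "samples", "rivers")
    }
    if config.scope:
        inputs["scope"] = _sha256(config.scope)

    # -- delimitation ------------------------------------------------------
    try:
        ml = parse_newick(Path(config.ml_tree).read_text())
        if not ml.is_binary():
            ml, n_res = resolve_polytomies(ml, seed=config.seed)
            logger.warning("resolved %d polytomies in the ML tree", n_res)
        minbr = config.min_branch_length
        if config.minbr_auto_sites:
            minbr = auto_min_branch_length(config.minbr_auto_sites)
        delim_cfg = DelimitationConfig(
            mode=config.mode,
            min_branch_length=minbr,
            outgroup=frozenset(config.outgroup),
            seed=config.seed,
            restarts=config.restarts,
            lrt_alpha=config.lrt_alpha,
        )
        delim = delimit_search(ml, delim_cfg)
        tip_to_lineage = delim.tip_to_lineage()
        logger.info("delimited %d lineages (%s mode)", delim.n_lineages, delim.mode)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("delimitation", str(exc)) from exc

    # -- geography ---------------------------------------------------------
    try:
        rivers = geo.load_rivers(Path(config.rivers).read_text())
        samples = pd.read_csv(config.samples, sep="\t", dtype={"sample_id": str})
        bank_table = geo.assign_banks_table(samples, rivers)
    except Exception as exc:
        raise PipelineError("geography", str(exc)) from exc

    # -- congruence --------------------------------------------------------
    try:
        dated = parse_newick(Path(config.dated_tree).read_text())
        if not dated.is_binary():
            dated, n_res = resolve_polytomies(dated, seed=config.seed)
            logger.warning("resolved %d polytomies in the dated tree", n_res)
        if config.scope:
            scope = {
                line.strip()
                for line in Path(config.scope).read_text().splitlines()
                if line.strip()
            }
        else:
            scope = set(tip_to_lineage) & set(dated.tip_label_set())
        nodes = cg.enumerate_lineage_divergences(dated, tip_to_lineage, scope)
        records = []
        for node in nodes:
            for river in rivers:
                records.append(
                    cg.classify_spatial_congruence(
                        dated,
                        node,
                        bank_table,
                        river,
                        tip_to_lineage,
                        scope,
                        config.min_determinate_per_side,
                    )
                )
        violations = {
            r.name: cg.find_barrier_violations(tip_to_lineage, bank_table, r)
            for r in rivers
        }
        summary = cg.summarize(records, rivers, violations)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("congruence", str(exc)) from exc

    # -- chronology --------------------------------------------------------
    try:
        posterior = parse_nexus_trees(
            Path(config.posterior).read_text(), config.burnin_fraction
        )
        age_by_node = {}
        for node in nodes:
            clade = dated.subtree_tip_labels(node) & scope
            age_by_node[node] = ch.mrca_ages_posterior(
                posterior, clade, level=config.hpd_level
            )
        temporal = {}
        for node in nodes:
            temporal[node] = {
                river.name: ch.temporal_congruence(
                    age_by_node[node].interval, river, config.temporal_rule
                ).congruent
                for river in rivers
            }
        synchrony = {}
        for river in rivers:
            congruent_nodes = {
                rec.node_id
                for rec in records
                if rec.river_name == river.name
                and rec.spatial_verdict == cg.CONGRUENT
            }
            if congruent_nodes:
                synchrony[river.name] = ch.synchrony_groups(
                    {
                        f"node_{n}": age_by_node[n].interval
                        for n in sorted(congruent_nodes)
                    }
                )
            else:
                synchrony[river.name] = []
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("chronology", str(exc)) from exc

    # -- report ------------------------------------------------------------
    spatial_by_node: dict[int, dict[str, str]] = {}
    for rec in records:
        spatial_by_node.setdefault(rec.node_id, {})[rec.river_name] = rec.spatial_verdict
    divergences = []
    for node in nodes:
        ap = age_by_node[node]
        rbh = {
            river.name: (
                spatial_by_node[node].get(river.name) == cg.CONGRUENT
                and temporal[node][river.name]
            )
            for river in rivers
        }
        divergences.append(
            {
                "node_id": node,
                "clade_tips": sorted(ap.clade_tips),
                "spatial": spatial_by_node.get(node, {}),
                "hpd_low": ap.hpd_low,
                "hpd_high": ap.hpd_high,
                "monophyly_fraction": ap.monophyly_fraction,
                "temporal": temporal[node],
                "rbh_congruent": rbh,
            }
        )
    per_river = {}
    for river in rivers:
        counts = summary.per_river[river.name]
        per_river[river.name] = dict(counts)
        per_river[river.name]["n_rbh_congruent"] = sum(
            1 for d in divergences if d["rbh_congruent"][river.name]
        )
        per_river[river.name]["min_age_ma"] = river.min_age_ma
    cfg_echo = asdict(config)
    return {
        "schema_version": SCHEMA_VERSION,
        "config": cfg_echo,
        "inputs": inputs,
        "seed": config.seed,
        "delimitation": {
            "mode": delim.mode,
            "n_lineages": delim.n_lineages,
            "log_likelihood": delim.log_likelihood,
            "degenerate": delim.degenerate,
            "n_excluded_edges": delim.n_excluded_edges,
            "lineages": {
                str(i): sorted(lin) for i, lin in enumerate(delim.lineages)
            },
        },
        "n_total_divergences": summary.n_total_divergences,
        "divergences": divergences,
        "per_river": per_river,
        "synchrony": synchrony,
        "violations": {k: list(v) for k, v in violations.items()},
        "low_support": [list(x) for x in summary.low_support],
    }


def intervals_only_mode(
    intervals: list[dict],
    rivers: list[geo.RiverBarrier],
    rule: str = "not-postdate",
) -> dict:
    """Assessment straight from published HPD intervals, no trees needed.

    ``intervals``: dicts with keys ``name``, ``river``, ``low``, ``high``.
    Runs synchrony grouping per river and, where a river definition with a
    minimum age is supplied, the temporal-congruence rule.
    """
    river_by_name = {r.name: r for r in rivers}
    by_river: dict[str, dict[str, tuple[float, float]]] = {}
    for item in intervals:
        low, high = float(item["low"]), float(item["high"])
        if low > high:
            raise ValueError(f"interval {item['name']!r}: low > high")
        by_river.setdefault(item["river"], {})[item["name"]] = (low, high)
    out: dict = {"schema_version": SCHEMA_VERSION, "rule": rule, "per_river": {}}
    for rname, ivals in by_river.items():
        entry: dict = {
            "n_intervals": len(ivals),
            "intervals": {k: list(v) for k, v in ivals.items()},
            "synchrony_groups": ch.synchrony_groups(ivals),
        }
        river = river_by_name.get(rname)
        if river is not None:
            congruent = sorted(
                name
                for name, iv in ivals.items()
                if ch.temporal_congruence(iv, river, rule).congruent
            )
            entry["min_age_ma"] = river.min_age_ma
            entry["congruent"] = congruent
            entry["n_congruent"] = len(congruent)
        out["per_river"][rname] = entry
    return out
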