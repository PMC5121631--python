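"""End-to-end orchestration: filter → community → network → indicators.

A single :class:`PipelineConfig` (or flat key=value config file) drives the
whole analysis and writes every stage artifact plus a consolidated
machine-readable summary, fully deterministically given one seed. The seed
expands into per-stage sub-seeds through a fixed splitting rule so each
stage can be re-run in isolation with identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import community, filtering, indicators, network, synthetic
from .data_model import (
    OtuTable,
    align,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    write_metadata,
    write_otu_table,
    write_taxonomy,
)
from .network import SASchedule, child_seed

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run", "parse_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    # inputs: either the three file paths, or a simulation preset
    otu_table: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    simulate_preset: str | None = None  # "paperlike"
    # filtering
    min_total_count: int = 3
    min_identity: float = 90.0
    # community
    metric: str = "jaccard"
    aggregate_mode: str = "presence"
    nmds_k: int = 2
    nmds_restarts: int = 20
    n_permutations: int = 999
    ploidy_levels: int = 2  # 2 = diploid vs polyploid, 3 = 2x/3x/4x
    # network
    n_null: int = 999
    sa_cooling: float = 0.95
    sa_f: float = 1.0
    sa_stall_max: int = 10
    # indicators
    site_unit: str = "population"
    n_perm_indicators: int = 999
    alpha: float = 0.05
    # bookkeeping
    seed: int = 0
    out_dir: str = "dactynet_out"

    def __post_init__(self) -> None:
        have_files = all(x is not None for x in (self.otu_table, self.metadata, self.taxonomy))
        if not have_files and self.simulate_preset is None:
            raise ValueError("provide the three input paths or a simulate preset")
        if self.simulate_preset not in (None, "paperlike"):
            raise ValueError("unknown preset; only 'paperlike' is defined")
        if self.site_unit not in ("population", "sample"):
            raise ValueError("site_unit must be 'population' or 'sample'")
        if self.ploidy_levels not in (2, 3):
            raise ValueError("ploidy_levels must be 2 or 3")


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the summary dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "provenance": {
            "seed": cfg.seed,
            "metric": cfg.metric,
            "aggregate_mode": cfg.aggregate_mode,
            "site_unit": cfg.site_unit,
            "ploidy_levels": cfg.ploidy_levels,
            "n_permutations": cfg.n_permutations,
            "n_null": cfg.n_null,
            "n_perm_indicators": cfg.n_perm_indicators,
            "sa_schedule": {
                "cooling": cfg.sa_cooling,
                "f": cfg.sa_f,
                "stall_max": cfg.sa_stall_max,
            },
            "min_total_count": cfg.min_total_count,
            "min_identity": cfg.min_identity,
        }
    }
    schedule = SASchedule(cooling=cfg.sa_cooling, f=cfg.sa_f, stall_max=cfg.sa_stall_max)
    truth = None

    # ---- load or simulate ------------------------------------------------
    stage = "load"
    try:
        if cfg.simulate_preset is not None:
            sim_cfg = synthetic.paperlike_preset(seed=child_seed(cfg.seed, 10))
            table, meta, taxonomy, truth = synthetic.simulate(sim_cfg)
            write_otu_table(table, out / "otu_table.tsv")
            write_metadata(meta, out / "metadata.tsv")
            write_taxonomy(taxonomy, out / "taxonomy.tsv")
            _dump(
                {
                    "otu_block": truth.otu_block,
                    "module_partition": truth.module_partition,
                    "planted_indicators": truth.planted_indicators,
                    "rare_otu_ids": truth.rare_otu_ids,
                    "junk_otu_ids": truth.junk_otu_ids,
                },
                out / "ground_truth.json",
            )
        else:
            table = read_otu_table(cfg.otu_table)
            meta = read_metadata(cfg.metadata)
            taxonomy = read_taxonomy(cfg.taxonomy)
        table = align(table, meta)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- filtering -------------------------------------------------------
    stage = "filter"
    try:
        filtered, report, _ = filtering.apply_filters(
            table,
            taxonomy,
            min_total_count=cfg.min_total_count,
            min_identity=cfg.min_identity,
        )
        write_otu_table(filtered, out / "filtered_table.tsv")
        _dump(report.to_dict(), out / "filter_report.json")
        prevalence = filtering.prevalence_by_group(filtered, meta, group_by="species")
        prev_summary = filtering.prevalence_summary(prevalence)
        venn = filtering.venn_by_ploidy(prevalence, meta)
        _dump(venn.to_dict(), out / "venn.json")
        _dump(
            {sp: sorted(otus) for sp, otus in prevalence.items()},
            out / "prevalence_species.json",
        )
        summary["filter"] = report.to_dict() | {"removed_ids": None}
        summary["filter"]["removed_ids"] = len(report.removed_ids)
        summary["prevalence"] = prev_summary
        summary["venn"] = venn.to_dict()
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- community: NMDS + PERMANOVA ------------------------------------
    stage = "community"
    try:
        agg = community.aggregate_by_species(filtered, meta, mode=cfg.aggregate_mode)
        dist = community.dissimilarity(agg, metric=cfg.metric)
        nm = community.nmds(
            dist,
            k=cfg.nmds_k,
            n_restarts=cfg.nmds_restarts,
            seed=child_seed(cfg.seed, 20),
        )
        coords = {
            i: [float(c) for c in row] for i, row in zip(nm.ids, nm.coordinates)
        }
        _dump(
            {"stress": nm.stress, "converged": nm.converged, "coordinates": coords},
            out / "nmds.json",
        )
        sp_attr = {m.species: m for m in meta}
        habitat_groups = {sp: sp_attr[sp].habitat.value for sp in agg.sample_ids}
        perm_h = community.permanova(
            dist,
            habitat_groups,
            n_permutations=cfg.n_permutations,
            seed=child_seed(cfg.seed, 21),
        )
        if cfg.ploidy_levels == 2:
            ploidy_groups = {
                sp: ("diploid" if sp_attr[sp].ploidy.value == "2x" else "polyploid")
                for sp in agg.sample_ids
            }
        else:
            ploidy_groups = {sp: sp_attr[sp].ploidy.value for sp in agg.sample_ids}
        perm_p = community.permanova(
            dist,
            ploidy_groups,
            n_permutations=cfg.n_permutations,
            seed=child_seed(cfg.seed, 22),
        )
        summary["nmds"] = {"stress": nm.stress, "k": cfg.nmds_k, "converged": nm.converged}
        summary["permanova_habitat"] = asdict(perm_h)
        summary["permanova_ploidy"] = asdict(perm_p)
        _dump(
            {"habitat": asdict(perm_h), "ploidy": asdict(perm_p)},
            out / "permanova.json",
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- network modularity ---------------------------------------------
    stage = "network"
    try:
        prevalence = filtering.prevalence_by_group(filtered, meta, group_by="species")
        net = network.build_network(prevalence)
        sig = network.significance(
            net,
            n_null=cfg.n_null,
            seed=child_seed(cfg.seed, 30),
            schedule=schedule,
        )
        part = network.detect_modules(
            net, seed=child_seed(child_seed(cfg.seed, 30), 1), schedule=schedule
        )
        _dump(
            {
                "assignment": part.assignment,
                "n_modules": part.n_modules,
                "l_s": part.l_s,
                "d_s": part.d_s,
                "M": part.M,
            },
            out / "partition.json",
        )
        _dump(
            {
                "M_obs": sig.M_obs,
                "null_mean": sig.null_mean,
                "null_sd": sig.null_sd,
                "p_value": sig.p_value,
                "n_null": len(sig.null_Ms),
                "n_modules": sig.n_modules_obs,
            },
            out / "modularity.json",
        )
        _write_module_matrix(net, part, out / "module_matrix.tsv")
        summary["modularity"] = {
            "M_obs": sig.M_obs,
            "null_mean": sig.null_mean,
            "null_sd": sig.null_sd,
            "p_value": sig.p_value,
            "n_modules": sig.n_modules_obs,
        }
        if truth is not None:
            from sklearn.metrics import adjusted_rand_score

            common = [u for u in part.assignment if u in truth.module_partition]
            ari = adjusted_rand_score(
                [truth.module_partition[u] for u in common],
                [part.assignment[u] for u in common],
            )
            summary["modularity"]["ari_vs_planted"] = float(ari)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- indicator analysis ----------------------------------------------
    stage = "indicators"
    try:
        if cfg.site_unit == "population":
            sites = community.aggregate_by_group(
                filtered, meta, attr="population_id", mode="summed_counts"
            )
            site_habitat = {m.population_id: m.habitat.value for m in meta}
        else:
            sites = filtered
            site_habitat = {m.sample_id: m.habitat.value for m in meta}
        res = indicators.indicator_test(
            sites,
            site_habitat,
            n_perm=cfg.n_perm_indicators,
            seed=child_seed(cfg.seed, 40),
            alpha=cfg.alpha,
        )
        lines = ["otu_id\tbest_group\tA\tB\tind_val\tp_value"]
        for r in res:
            lines.append(
                f"{r.otu_id}\t{'+'.join(sorted(r.best_group))}\t{r.A:.6g}\t"
                f"{r.B:.6g}\t{r.ind_val:.6g}\t{'' if r.p_value is None else f'{r.p_value:.6g}'}"
            )
        (out / "indicators.tsv").write_text("\n".join(lines) + "\n")
        signif = [
            {
                "otu_id": r.otu_id,
                "best_group": sorted(r.best_group),
                "ind_val": r.ind_val,
                "p_value": r.p_value,
            }
            for r in res
            if r.p_value is not None and r.p_value <= cfg.alpha
        ]
        summary["indicators"] = {
            "n_tested": len(res),
            "n_significant": len(signif),
            "alpha": cfg.alpha,
            "significant": signif,
        }
        if truth is not None:
            hits = {s["otu_id"] for s in signif}
            planted = set(truth.planted_indicators)
            summary["indicators"]["planted_recovered"] = len(hits & planted)
            summary["indicators"]["n_planted"] = len(planted)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    _dump(summary, out / "summary.json")
    (out / "report.txt").write_text(_text_report(summary))
    return summary


def _write_module_matrix(net, part, path: Path) -> None:
    """Species × OTU matrix reordered by module; 1 = within-module link,
    2 = between-module link, 0 = no link."""
    sp_order = sorted(
        range(len(net.species_ids)),
        key=lambda i: (part.assignment[net.species_ids[i]], net.species_ids[i]),
    )
    ot_order = sorted(
        range(len(net.otu_ids)),
        key=lambda j: (part.assignment[net.otu_ids[j]], net.otu_ids[j]),
    )
    lines = ["species\t" + "\t".join(net.otu_ids[j] for j in ot_order)]
    for i in sp_order:
        row = [net.species_ids[i]]
        for j in ot_order:
            if net.incidence[i, j] == 0:
                row.append("0")
            elif part.assignment[net.species_ids[i]] == part.assignment[net.otu_ids[j]]:
                row.append("1")
            else:
                row.append("2")
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def _text_report(summary: dict) -> str:
    f = summary["filter"]
    m = summary["modularity"]
    ph = summary["permanova_habitat"]
    pp = summary["permanova_ploidy"]
    ind = summary["indicators"]
    lines = [
        "dactynet pipeline report",
        "========================",
        "",
        f"OTUs: {f['n_input_otus']} input, {f['n_removed_rare']} rare removed, "
        f"{f['n_removed_nonmycorrhizal']} non-mycorrhizal removed, "
        f"{f['n_retained']} retained",
        f"Per-species OTU richness: min {summary['prevalence']['min']}, "
        f"max {summary['prevalence']['max']}, mean {summary['prevalence']['mean']:.1f}",
        "",
        f"NMDS stress (k={summary['nmds']['k']}): {summary['nmds']['stress']:.4f}",
        f"PERMANOVA habitat: pseudo-F = {ph['pseudo_F']:.3f}, P = {ph['p_value']:.4g}",
        f"PERMANOVA ploidy:  pseudo-F = {pp['pseudo_F']:.3f}, P = {pp['p_value']:.4g}",
        "",
        f"Modularity: M_obs = {m['M_obs']:.4f}, M_random = {m['null_mean']:.4f} "
        f"± {m['null_sd']:.4f}, P = {m['p_value']:.4g}, {m['n_modules']} modules",
        "",
        f"Indicator OTUs significant at alpha={ind['alpha']}: {ind['n_significant']}"
        f" of {ind['n_tested']}",
    ]
    for s in ind["significant"]:
        lines.append(
            f"  {s['otu_id']}: {'+'.join(s['best_group'])} "
            f"(IndVal {s['ind_val']:.3f}, P {s['p_value']:.4g})"
        )
    return "\n".join(lines) + "\n"


_BOOL = {"true": True, "false": False}


def parse_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file (one pair per line, # comments)."""
    kwargs: dict[str, Any] = {}
    types = {f.name: f.type for f in PipelineConfig.__dataclass_fields__.values()}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, val = (x.strip() for x in line.split("=", 1))
        if key not in types:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if val.lower() in _BOOL:
            kwargs[key] = _BOOL[val.lower()]
        else:
            for cast in (int, float):
                try:
                    kwargs[key] = cast(val)
                    break
                except ValueError:
                    continue
            else:
                kwargs[key] = val
    return PipelineConfig(**kwargs)
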