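"""End-to-end orchestration: simulate/load -> preprocess -> all analyses.

The run report (a JSON-serialisable dict) is the single source of truth:
every count, fraction, R^2 and p-value appears next to the parameters and
seed that produced it.  TSV outputs are derived views.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import community_data as cd
from . import compartment_source as cs
from . import ordination_stats as ords
from . import set_partition as sp
from . import synthetic_data as syn
from . import transmission as tr

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable to YAML/JSON."""

    # input mode: either 'simulate' (built-in generator) or 'files'
    mode: str = "simulate"
    counts_path: str | None = None
    counts_format: str = "tsv"
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    marker: str = "16S"
    min_total_reads: int = 30
    min_prevalence: int = 3
    rarefaction_depth: int = 1000
    focal_field: str = "F1"
    detection_min_count: int = 1
    detection_min_samples: int = 1
    top_asv_threshold: float = 0.01
    n_permutations: int = 999
    seed: int = 0
    sim: dict[str, Any] = field(default_factory=dict)
    output_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _detection_sets_by(table: cd.CountTable, column: str, min_count: int,
                       min_samples: int) -> dict[str, sp.DetectionSet]:
    out = {}
    for value in sorted(table.metadata[column].dropna().unique()):
        ids = table.samples_where(**{column: value})
        if not ids:
            continue
        group = sp.SampleGroup(str(value), frozenset(ids))
        out[str(value)] = sp.detection_set(table, group, min_count, min_samples)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage and return the machine-readable report."""
    report: dict[str, Any] = {
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }
    mc, ms = config.detection_min_count, config.detection_min_samples

    # ------------------------------------------------------------------ input
    try:
        if config.mode == "simulate":
            sim_cfg = syn.SimConfig(**{"rng_seed": config.seed, **config.sim})
            seed_table, truth = syn.simulate_seed_tubers(sim_cfg)
            next_table, truth = syn.simulate_next_generation(truth, sim_cfg)
            comp_table, truth = syn.simulate_compartments_and_sprout(truth, sim_cfg)
            taxonomy = syn.synthetic_taxonomy(
                sorted(set(seed_table.asv_ids) | set(next_table.asv_ids))
            )
            tables = {"seed": seed_table, "next": next_table, "compartments": comp_table}
        elif config.mode == "files":
            if not (config.counts_path and config.metadata_path):
                raise ValueError("files mode needs counts_path and metadata_path")
            metadata = cd.read_metadata(config.metadata_path)
            table = cd.read_count_table(
                config.counts_path, format=config.counts_format, metadata=metadata
            )
            taxonomy = (
                cd.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
            )
            st = set(table.metadata["sample_type"])
            tables = {
                "seed": table.subset_samples(table.samples_where(sample_type="seed_tuber")),
                "next": table.subset_samples(table.samples_where(
                    sample_type=[t for t in ("daughter_tuber", "root") if t in st])),
                "compartments": table.subset_samples(table.samples_where(
                    sample_type=[t for t in (*cs.COMPARTMENTS, "sprout") if t in st])),
            }
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc

    # ------------------------------------------------------------- preprocess
    # fixed order: off-target removal -> rare-ASV filter -> rarefaction
    try:
        processed: dict[str, cd.CountTable] = {}
        prep_report: dict[str, Any] = {"order": ["offtarget", "rare_filter", "rarefy"]}
        logger.info("preprocessing order: offtarget -> rare_filter -> rarefy")
        for name, tab in tables.items():
            if taxonomy is not None:
                tab = cd.remove_offtarget_taxa(tab, taxonomy, config.marker)
            tab = cd.filter_rare_asvs(tab, config.min_total_reads, config.min_prevalence)
            tab, dropped = cd.rarefy(tab, config.rarefaction_depth, config.seed)
            processed[name] = tab
            prep_report[name] = {
                "n_samples": tab.n_samples,
                "n_asvs": tab.n_asvs,
                "dropped_below_depth": dropped,
                "rarefaction_depth": config.rarefaction_depth,
                "seed": config.seed,
            }
        report["stages"]["preprocess"] = prep_report
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    # ------------------------------------------------- set partition / unique
    try:
        seed_tab, next_tab, comp_tab = (
            processed["seed"], processed["next"], processed["compartments"],
        )
        by_type: dict[str, sp.DetectionSet] = {}
        for name, tab in (("seed_tuber", seed_tab),):
            grp = sp.SampleGroup(name, frozenset(tab.sample_ids))
            by_type[name] = sp.detection_set(tab, grp, mc, ms)
        for st in ("daughter_tuber", "root"):
            ids = next_tab.samples_where(sample_type=st)
            by_type[st] = sp.detection_set(
                next_tab, sp.SampleGroup(st, frozenset(ids)), mc, ms
            )
        partition = sp.overlap_partition(
            [by_type["seed_tuber"], by_type["daughter_tuber"], by_type["root"]]
        )
        report["stages"]["overlap"] = {
            "detection_rule": [mc, ms],
            "group_totals": {n: partition.group_total(n) for n in partition.group_names},
            "regions": {"&".join(sorted(k)): len(v) for k, v in partition.regions.items()},
            "shared_daughter_with_root": sp.shared_fraction(
                partition, "daughter_tuber", {"root"}),
            "shared_daughter_with_seed": sp.shared_fraction(
                partition, "daughter_tuber", {"seed_tuber"}),
            "shared_root_with_seed": sp.shared_fraction(partition, "root", {"seed_tuber"}),
        }

        field_sets_seed = {}
        for f in sorted(seed_tab.metadata["production_field"].unique()):
            ids = seed_tab.samples_where(production_field=f)
            field_sets_seed[f] = sp.detection_set(
                seed_tab, sp.SampleGroup(f, frozenset(ids)), mc, ms
            )
        unique_seed = sp.field_unique_asvs(field_sets_seed, config.focal_field)
        report["stages"]["field_unique"] = {
            "focal_field": config.focal_field,
            "focal_total": unique_seed.focal_total,
            "n_unique": len(unique_seed.unique_asvs),
            "unique_fraction": unique_seed.unique_fraction,
            "unique_percent": unique_seed.percent(1),
        }
    except Exception as exc:
        raise StageError("set_partition", exc) from exc

    # ------------------------------------------------------------ transmission
    try:
        focal_seed_ids = seed_tab.samples_where(production_field=config.focal_field)
        focal_seed_set = sp.detection_set(
            seed_tab, sp.SampleGroup("seed_tuber", frozenset(focal_seed_ids)), mc, ms
        )
        trans_report = {}
        for st in ("daughter_tuber", "root"):
            ids = next_tab.samples_where(sample_type=st, production_field=config.focal_field)
            dest_set = sp.detection_set(next_tab, sp.SampleGroup(st, frozenset(ids)), mc, ms)
            summary = tr.classify_transmission(focal_seed_set, dest_set)
            dest_rel = cd.to_relative_abundance(next_tab.subset_samples(ids))
            summary = tr.abundance_accounting(dest_rel, summary)
            trans_report[st] = {
                "n_source": summary.n_source,
                "n_dest": summary.n_dest,
                "n_shared": len(summary.shared),
                "n_lost": len(summary.lost),
                "n_acquired": len(summary.acquired),
                "percents": summary.percents(),
                "dest_abundance": summary.dest_abundance,
            }
        report["stages"]["transmission"] = trans_report
    except Exception as exc:
        raise StageError("transmission", exc) from exc

    # ------------------------------------------------------------ compartments
    try:
        comp_sets = {}
        for comp in cs.COMPARTMENTS:
            ids = comp_tab.samples_where(sample_type=comp)
            comp_sets[comp] = sp.detection_set(
                comp_tab, sp.SampleGroup(comp, frozenset(ids)), mc, ms
            )
        sprout_tab = comp_tab.subset_samples(comp_tab.samples_where(sample_type="sprout"))
        sprout_tab = sprout_tab.subset_asvs(
            sprout_tab.data.columns[sprout_tab.data.sum(axis=0) > 0]
        )
        attribution = cs.source_attribution(sprout_tab, comp_sets, mc, ms)
        sharing = cs.per_compartment_sharing(attribution)
        top = cs.top_abundant_asvs(
            cd.to_relative_abundance(sprout_tab), config.top_asv_threshold
        )
        report["stages"]["compartment_source"] = {
            "n_sprout_asvs": attribution.n_sprout_asvs,
            "n_in_any_compartment": attribution.n_in_any,
            "n_in_all_compartments": attribution.n_in_all,
            "n_sprout_unique": len(attribution.sprout_unique),
            "sprout_unique_abundance": attribution.abundance_of(attribution.sprout_unique),
            "per_compartment": {c: {"n": n, "percent": p} for c, (n, p) in sharing.items()},
            "top_asvs": {
                "threshold": top.threshold,
                "n": len(top.top_asvs),
                "cumulative_share": top.cumulative_share,
            },
        }
    except Exception as exc:
        raise StageError("compartment_source", exc) from exc

    # --------------------------------------------------------------- ordination
    try:
        dm = ords.bray_curtis(cd.to_relative_abundance(seed_tab))
        grouping = seed_tab.metadata["production_field"]
        perm = ords.permanova(
            dm, grouping, config.n_permutations, config.seed, factor="production_field"
        )
        var_perm = ords.permanova(
            dm, seed_tab.metadata["variety"], config.n_permutations,
            config.seed, factor="variety",
        )
        rich = ords.richness_and_kw(
            comp_tab.subset_samples(
                comp_tab.samples_where(sample_type=list(cs.COMPARTMENTS))
            ),
            comp_tab.metadata["sample_type"],
        )
        report["stages"]["ordination"] = {
            "permanova": [
                {
                    "factor": r.factor, "R2": float(r.r2), "pseudo_F": float(r.pseudo_f),
                    "p": float(r.p_value), "n_permutations": r.n_permutations,
                    "seed": r.rng_seed,
                }
                for r in (perm, var_perm)
            ],
            "compartment_richness_mean": {
                c: float(rich.richness[
                    comp_tab.samples_where(sample_type=c)].mean())
                for c in cs.COMPARTMENTS
            },
            "richness_kw": {"H": rich.h_statistic, "p": rich.p_value},
        }
    except Exception as exc:
        raise StageError("ordination", exc) from exc

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        pd.DataFrame(partition.to_records()).to_csv(
            out / "overlap_partition.tsv", sep="\t", index=False
        )
        (out / "MANIFEST").write_text("report.json\noverlap_partition.tsv\n")
    return report
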