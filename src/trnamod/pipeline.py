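"""End-to-end orchestration: call -> transfer -> patterns -> report.

Stage outputs are written into a staging directory and atomically moved into
place, so a failed run never leaves partial results behind.  Every output
embeds the configuration hash in its header; identical config + inputs give
byte-identical outputs (timestamps go to the log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, calling, homology, io, patterns, type_inference
from .simulate import SimulationConfig, simulate_scenario

log = logging.getLogger("trnamod")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "trnamod_run"
    calling: calling.CallingConfig = field(
        default_factory=calling.CallingConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cooccurrence_pairs: tuple = (("6", "67"), ("10", "26"))
    enrichment_focal: tuple = ("10", "26")
    enrichment_stem_pairs: tuple = (("10", "25"), ("13", "22"), ("12", "23"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("seed", "outdir"):
            if key in raw:
                setattr(cfg, key, raw[key])
        for section, target in (("calling", cfg.calling),
                                ("simulation", cfg.simulation)):
            for k, v in (raw.get(section) or {}).items():
                if not hasattr(target, k):
                    raise ValueError(f"unknown {section} option {k!r}")
                setattr(target, k, v)
        if "seed" in raw:
            cfg.simulation.seed = raw["seed"]
        return cfg

    def config_hash(self) -> str:
        # hash only settings that affect results; output location excluded
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in sorted(obj.items(),
                                                            key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if hasattr(obj, "__dict__"):
                return clean(vars(obj))
            return obj
        payload = clean(asdict(self))
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (f"trnamod {__version__}\n"
            f"config-hash {config.config_hash()}\n"
            f"seed {config.seed}")


def run_pipeline(config: RunConfig, scenario: dict | None = None) -> Path:
    """Run all stages on synthetic (or supplied) data; return the run dir.

    ``scenario`` defaults to :func:`trnamod.simulate.simulate_scenario` with
    the configured seed.  Writes call tables, predicted annotations, the
    species-pair comparison report, pattern tables and a five-section
    summary report.
    """
    config.simulation.seed = config.seed
    outdir = Path(config.outdir)
    header = _provenance(config)
    staging = Path(tempfile.mkdtemp(prefix=".trnamod_staging_",
                                    dir=outdir.parent if outdir.parent.exists()
                                    else None))
    try:
        if scenario is None:
            log.info("simulating default scenario (seed=%d)", config.seed)
            scenario = simulate_scenario(config.simulation)
        coverage, truth = scenario["coverage"], scenario["truth"]
        clade_map = scenario["clade_map"]
        io.write_coverage(coverage, staging / "coverage.tsv", header)
        io.write_annotations(truth, staging / "truth_annotations.tsv", header)

        log.info("calling modifications (%d coverage rows)", len(coverage))
        calls = calling.call_modifications(coverage, truth, config.calling)

        profiles = type_inference.build_type_profiles(calls, truth)
        calls = type_inference.assign_types(calls, profiles, truth, clade_map)
        io.write_calls(calls, staging / "calls.tsv", header_comment=header)
        io._write_tsv(type_inference.profiles_to_frame(profiles),
                      staging / "type_profiles.tsv", header)

        log.info("homology transfer within clades")
        comparisons, predicted_all = [], []
        species = sorted(clade_map)
        for i, src in enumerate(species):
            for tgt in species[i + 1:]:
                if clade_map[src] != clade_map[tgt]:
                    continue
                pairs, *_ = homology.match_orthologs(
                    scenario["seqs"][src], scenario["seqs"][tgt], src, tgt)
                src_ann = truth[truth["species"] == src]
                predicted, _rejected = homology.transfer_annotations(
                    pairs, src_ann, calls[calls["species"] == tgt])
                if len(predicted):
                    predicted_all.append(predicted)
                    comparisons.append(homology.compare_species(
                        calls[calls["species"] == src], predicted,
                        calls[calls["species"] == tgt]))
        predicted = (pd.concat(predicted_all, ignore_index=True)
                     if predicted_all else pd.DataFrame(
                         columns=["species", "trna", "position", "code",
                                  "source", "confidence", "source_species",
                                  "source_trna"]))
        io.write_annotations(predicted, staging / "predicted_annotations.tsv",
                             header)
        io._write_tsv(homology.comparison_report(comparisons),
                      staging / "comparisons.tsv", header)

        log.info("pattern analyses")
        annotations = pd.concat(
            [truth, predicted[["species", "trna", "position", "code",
                               "source"]]], ignore_index=True) \
            if len(predicted) else truth
        cooc_frames = []
        for p, q in config.cooccurrence_pairs:
            res = patterns.cooccurrence(calls, (p, q), affected_base="G",
                                        annotations=annotations,
                                        grouping=clade_map)
            cooc_frames.append(patterns.cooccurrence_to_frame(res))
        cooc = pd.concat(cooc_frames, ignore_index=True)
        io._write_tsv(cooc, staging / "cooccurrence.tsv", header)

        summary = patterns.modification_frequency_summary(calls, clade_map)
        io._write_tsv(summary, staging / "frequency_summary.tsv", header)

        enrich_frames = []
        for focal in config.enrichment_focal:
            res = patterns.identity_element_enrichment(
                calls, focal, [tuple(p) for p in config.enrichment_stem_pairs])
            df = res.table.copy()
            df.insert(0, "focal_position", focal)
            enrich_frames.append(df)
        enrichment = pd.concat(enrich_frames, ignore_index=True)
        io._write_tsv(enrichment, staging / "enrichment.tsv", header)

        _write_report(staging / "report.txt", header, calls, comparisons,
                      cooc, summary, enrichment, config)

        outdir.mkdir(parents=True, exist_ok=True)
        for item in staging.iterdir():
            target = outdir / item.name
            if target.exists():
                target.unlink()
            shutil.move(str(item), target)
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    log.info("run complete: %s", outdir)
    return outdir


def _write_report(path: Path, header: str, calls, comparisons, cooc,
                  summary, enrichment, config: RunConfig) -> None:
    lines = [f"# {line}" for line in header.splitlines()]
    lines += ["", "## 1. Confident modification calls per species", ""]
    conf = calling.confident(calls)
    for species, sub in conf.groupby("species"):
        n_high = int((sub["confidence"] == "high").sum())
        n_mod = int((sub["confidence"] == "moderate").sum())
        lines.append(f"{species}\thigh={n_high}\tmoderate={n_mod}")

    lines += ["", "## 2. Species-pair concordance", ""]
    for comp in comparisons:
        n_out = int(comp.sites["outlier"].sum()) if len(comp.sites) else 0
        lines.append(
            f"{comp.source_species} vs {comp.target_species}\t"
            f"n={len(comp.sites)}\tpearson_r={comp.pearson_r:.4f}\t"
            f"outliers={n_out}")
        for _, o in comp.outliers.iterrows():
            lines.append(f"  outlier\t{o['trna']}\t{o['code']}"
                         f"\tposition {o['position']}")

    lines += ["", "## 3. Co-occurrence / mutual exclusivity", ""]
    for _, r in cooc.iterrows():
        lines.append(
            f"{r['group']}\t{r['position_p']}/{r['position_q']}\t"
            f"both={r['n_both']}\tp_only={r['n_p_only']}\t"
            f"q_only={r['n_q_only']}\tneither={r['n_neither']}\t"
            f"OR={r['odds_ratio']:.3g}\tp={r['p_value']:.3g}")

    lines += ["", "## 4. Modification frequency by group", ""]
    frequent = summary[summary["n_modified"] > 0]
    for _, r in frequent.iterrows():
        lines.append(f"{r['group']}\t{r['ref_base']}{r['position']}\t"
                     f"{r['n_modified']}/{r['n_eligible']}"
                     f"\t{r['fraction']:.2f}")

    lines += ["", "## 5. Identity-element enrichment", ""]
    for _, r in enrichment.iterrows():
        lines.append(
            f"focal {r['focal_position']}\tpair {r['stem_pair']}\t"
            f"{r['identity']}\tOR={r['odds_ratio']:.3g}"
            f"\tp={r['p_value']:.3g}")

    lines += ["", "## Settings in effect", ""]
    for k, v in sorted(vars(config.calling).items()):
        lines.append(f"calling.{k} = {v}")
    path.write_text("\n".join(lines) + "\n")
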