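"""End-to-end orchestration: simulate -> filter -> profile -> diff -> dcc ->
classify -> report, driven by a YAML/JSON scenario config.

Stage artifacts are plain TSV/JSON so each stage is independently
re-runnable; a rerun with the same config and seed reproduces identical
numerical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .dcc import compute_dcc, find_dcc_peaks, phase_partition
from .differential import (
    DEFAULT_BASELINE_REGIONS,
    antiphase_correlation,
    baseline_stats,
    delta_profile,
    differential_to_tsv,
    positionwise_significance,
)
from .errors import ConfigurationError, DataError
from .fragment_io import (
    LengthFilter,
    filter_by_length,
    write_fragments_bed,
    write_fragments_fasta,
)
from .profiles import SHLMap, mono_profile, profile_to_tsv, smooth3, symmetrize, w_profile
from .rotational import PhaseTemplate, classify_population
from .synthetic import (
    OccurrenceLaw,
    PopulationSpec,
    ShiftSpec,
    SyntheticPopulation,
    composition_from_dict,
    make_shifted_population,
    sample_population,
)

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    return cfg


def load_scenario(name: str) -> dict:
    """Load a packaged scenario config (null, h2a_like, h4_like)."""
    ref = resources.files("nucpos.scenarios").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise ConfigurationError(f"unknown packaged scenario {name!r}")
    return yaml.safe_load(ref.read_text())


def _population_spec(cfg: Mapping, contig: str, contig_length: int, seed: int) -> PopulationSpec:
    occ = cfg.get("occurrence", {"law": "fixed", "value": 1})
    return PopulationSpec(
        n_positions=int(cfg["n_positions"]),
        composition=composition_from_dict(cfg.get("composition", {})),
        occurrence=OccurrenceLaw(
            law=occ.get("law", "fixed"),
            value=int(occ.get("value", 1)),
            mu=float(occ.get("mu", 0.0)),
            sigma=float(occ.get("sigma", 1.0)),
        ),
        contig=contig,
        contig_length=contig_length,
        length_weights={int(k): float(v) for k, v in cfg.get(
            "length_weights", {147: 1.0}
        ).items()},
        seed=seed,
    )


def simulate_populations(
    config: Mapping, seed: int
) -> tuple[SyntheticPopulation, SyntheticPopulation]:
    """Build the reference population and its comparison per the config."""
    contig = config.get("contig", "chrS")
    contig_length = int(config.get("contig_length", 1_000_000))
    pops = config["populations"]
    ref = sample_population(
        _population_spec(pops["reference"], contig, contig_length, seed)
    )
    cmp_cfg = pops["comparison"]
    override = None
    if "composition_override" in cmp_cfg:
        override = composition_from_dict(cmp_cfg["composition_override"])
    if cmp_cfg.get("derive") == "shifted":
        sh = cmp_cfg.get("shifts", {})
        shifts = ShiftSpec(
            unmoved_fraction=float(sh.get("unmoved", 0.0)),
            inphase_fraction=float(sh.get("inphase", 1.0)),
            counterphase_fraction=float(sh.get("counterphase", 0.0)),
            shift_ns={int(k): float(v) for k, v in sh.get("shift_ns", {1: 1.0}).items()},
            seed=seed + 1,
        )
        cmp_pop = make_shifted_population(ref, shifts, composition_override=override)
    else:
        spec = _population_spec(cmp_cfg, contig, contig_length, seed + 1)
        if override is not None:
            from dataclasses import replace

            spec = replace(spec, composition=override)
        cmp_pop = sample_population(spec)
    return ref, cmp_pop


def _checksum(fragments) -> str:
    h = hashlib.sha256()
    for frag in fragments:
        h.update(f"{frag.contig}:{frag.start}-{frag.end}:{frag.sequence}".encode())
    return h.hexdigest()[:16]


def run_pipeline(
    config: Mapping[str, Any], outdir: str | Path, seed: int = 0
) -> dict:
    """Execute every stage on a simulated two-population scenario.

    Writes per-stage TSV/JSON artifacts plus ``report.json`` and the resolved
    config, and returns the report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = config.get("analysis", {})
    period = float(analysis.get("period", 10.4))
    shl_map = SHLMap(period)
    report: dict[str, Any] = {
        "scenario": config.get("name", "unnamed"),
        "seed": seed,
        "version": __version__,
    }

    stage = "simulate"
    try:
        ref_pop, cmp_pop = simulate_populations(config, seed)
        labels = (
            config["populations"]["reference"].get("label", "ref"),
            config["populations"]["comparison"].get("label", "cmp"),
        )
        for pop, label in ((ref_pop, labels[0]), (cmp_pop, labels[1])):
            write_fragments_fasta(pop.fragments, outdir / f"{label}.fragments.fasta")
            write_fragments_bed(pop.fragments, outdir / f"{label}.fragments.bed")
            pop.dyad_table.to_tsv(outdir / f"{label}.dyads.tsv")
            (outdir / f"{label}.truth.json").write_text(json.dumps(pop.truth, indent=1))

        stage = "filter"
        lf_cfg = analysis.get("length_filter", {"min": 146, "max": 149})
        length_filter = LengthFilter(int(lf_cfg["min"]), int(lf_cfg["max"]))
        ref_frags = filter_by_length(ref_pop.fragments, length_filter)
        cmp_frags = filter_by_length(cmp_pop.fragments, length_filter)
        report["fragments"] = {
            labels[0]: {"total": len(ref_pop.fragments), "kept": len(ref_frags)},
            labels[1]: {"total": len(cmp_pop.fragments), "kept": len(cmp_frags)},
        }
        report["input_checksums"] = {
            labels[0]: _checksum(ref_pop.fragments),
            labels[1]: _checksum(cmp_pop.fragments),
        }

        stage = "profile"
        profiles = {}
        for frags, label in ((ref_frags, labels[0]), (cmp_frags, labels[1])):
            raw_w = w_profile(frags)
            raw_a = mono_profile(frags, "A", motif="A")
            raw_t = mono_profile(frags, "T", motif="T")
            sm_w = symmetrize(smooth3(raw_w))
            sm_a = symmetrize(
                smooth3(raw_a), complement_aware=True, complement_profile=smooth3(raw_t)
            )
            sm_t = symmetrize(
                smooth3(raw_t), complement_aware=True, complement_profile=smooth3(raw_a)
            )
            profiles[label] = {
                "raw_w": raw_w, "raw_a": raw_a, "raw_t": raw_t,
                "w": sm_w, "a": sm_a, "t": sm_t,
            }
            for key in ("w", "a", "t"):
                profile_to_tsv(
                    profiles[label][key], outdir / f"{label}.{key}.profile.tsv", shl_map
                )

        stage = "diff"
        regions = tuple(
            tuple(r) for r in analysis.get("baseline_regions", DEFAULT_BASELINE_REGIONS)
        )
        diff = delta_profile(
            profiles[labels[0]]["w"], profiles[labels[1]]["w"], *labels
        )
        mean, sd = baseline_stats(diff, regions)
        diff.pvalues = positionwise_significance(
            profiles[labels[0]]["raw_w"].counts,
            profiles[labels[0]]["raw_w"].coverage,
            profiles[labels[1]]["raw_w"].counts,
            profiles[labels[1]]["raw_w"].coverage,
        )
        differential_to_tsv(diff, outdir / "delta_w.tsv")
        corr = antiphase_correlation(diff, profiles[labels[0]]["w"], shl_map=shl_map)
        n_sig = int(np.sum(diff.pvalues < 0.05))
        report["delta_w"] = {
            "baseline_mean": mean,
            "baseline_sd": sd,
            "baseline_regions": [list(r) for r in regions],
            "n_significant": n_sig,
            "significant_positions": [
                int(p) for p in diff.positions_1based[diff.pvalues < 0.05]
            ],
            "peak_position": int(np.argmax(diff.delta) + 1),
            "peak_delta": float(np.max(diff.delta)),
            "antiphase_correlation": corr,
        }

        stage = "dcc"
        dcc_cfg = analysis.get("dcc", {})
        result = compute_dcc(
            ref_pop.dyad_table,
            cmp_pop.dyad_table,
            max_dist=int(dcc_cfg.get("max_dist", 100)),
            min_occurrence=int(dcc_cfg.get("min_occurrence", 0)),
        )
        peaks = find_dcc_peaks(result)
        in_mass, cp_mass, cp_frac = phase_partition(result)
        result.to_tsv(outdir / "dcc.tsv")
        report["dcc"] = {
            "peaks": [asdict(p) for p in peaks[:10]],
            "inphase_mass": in_mass,
            "counterphase_mass": cp_mass,
            "counterphase_fraction": cp_frac,
        }

        stage = "classify"
        cls_cfg = analysis.get("classifier", {})
        template = PhaseTemplate(period=period)
        threshold = float(cls_cfg.get("threshold", 0.1))
        report["classification"] = {}
        for frags, label in ((ref_frags, labels[0]), (cmp_frags, labels[1])):
            cls = classify_population(
                frags, template, threshold, subset_profiles=False
            )
            report["classification"][label] = cls.summary()

        stage = "report"
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        (outdir / "resolved_config.yaml").write_text(
            yaml.safe_dump({**dict(config), "seed": seed}, sort_keys=False)
        )
    except (ConfigurationError, DataError):
        raise
    except Exception as exc:  # pragma: no cover - stage-labeled failure path
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
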