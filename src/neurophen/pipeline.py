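"""Config-driven orchestration: simulate -> analyze -> report.

A run is described by a single YAML config with one section per stage; all
randomness funnels through one seed. The report echoes parameters, records a
SHA-256 hash of every file written, and is byte-identical when the same
config and seed are re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import calcium, io, lfp, proteomics, synthdata, units

logger = logging.getLogger("neurophen.pipeline")


class ConfigError(ValueError):
    """A config key or value violates the documented schema."""


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "log_level", "simulate", "calcium", "units", "lfp", "proteomics"},
    "simulate": {"calcium", "spikes", "lfp", "proteome"},
    "simulate.calcium": {
        "n_rois", "duration_s", "fs", "frac_hyper", "rate_hyper", "rate_base",
        "kernel_params", "neuropil_coupling", "noise_sd", "snr", "baseline",
        "background_sd", "animal_id", "genotype", "layer",
    },
    "simulate.spikes": {
        "n_units", "duration_s", "rate_log_mean", "rate_log_sd", "depth_range",
        "frac_contaminated", "contamination_fraction", "dead_time_ms",
    },
    "simulate.lfp": {
        "duration_s", "fs_raw", "n_channels", "band_power_targets",
        "common_offset_amplitude",
    },
    "simulate.proteome": {
        "n_proteins", "group_sizes", "frac_de", "lfc_location", "lfc_scale",
        "up_fraction", "var_mean", "var_shape", "var_heterogeneity", "frac_ecm",
        "ecm_de_odds",
    },
    "calcium": {"input", "threshold_mult", "min_duration_frames", "neuropil_coef"},
    "units": {"spikes", "units", "duration_s", "bin_s", "refractory_ms", "max_violation"},
    "lfp": {"input", "fs_out", "window_s", "overlap"},
    "proteomics": {
        "abundance", "samples", "group_a", "group_b", "alpha", "fc_cut",
        "gene_sets", "regulators", "min_valid_per_group",
    },
}


def validate_config(config: dict) -> None:
    """Reject unknown keys, naming the offending dotted path."""
    def walk(section: dict, prefix: str) -> None:
        allowed = _SCHEMA.get(prefix)
        if allowed is None:
            return
        for key, value in section.items():
            if key not in allowed:
                dotted = f"{prefix}.{key}" if prefix else key
                raise ConfigError(f"unknown config key {dotted!r}")
            child = f"{prefix}.{key}" if prefix else key
            if isinstance(value, dict) and child in _SCHEMA:
                walk(value, child)

    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    walk(config, "")


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    validate_config(config)
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: dict, out_dir=None, seed: int | None = None) -> dict:
    """Execute the configured stages in dependency order and write a report.

    Returns the report dict; ``report.json`` plus every stage output lands in
    ``out_dir``. Missing input files raise with stage context; unknown keys
    are rejected up front.
    """
    validate_config(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "neurophen_out"))
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": seed, "stages": {}, "files": {}, "warnings": []}
    artifacts: dict = {}

    def record(path: Path) -> None:
        report["files"][str(path.name)] = _sha256(path)

    sim = config.get("simulate") or {}
    if sim:
        stage: dict = {"parameters": sim}
        if "calcium" in sim:
            rec, truth = synthdata.gen_calcium(**sim["calcium"], seed=seed)
            artifacts["calcium_recording"] = rec
            artifacts["calcium_truth"] = truth
            p = io.write_recording_csv(rec, out / "sim_calcium.csv")
            record(p)
            record(p.with_suffix(".meta.json"))
            truth_path = out / "sim_calcium.truth.json"
            truth_path.write_text(json.dumps({
                "rate_per_roi": truth.rate_per_roi,
                "class_per_roi": truth.class_per_roi,
                "event_times_per_roi": [t for t in truth.event_times_per_roi],
                "seed": truth.seed,
            }, default=_json_default, sort_keys=True))
            record(truth_path)
        if "spikes" in sim:
            sunits, struth = synthdata.gen_spikes(**sim["spikes"], seed=seed)
            artifacts["spike_units"] = sunits
            artifacts["spike_truth"] = struth
            p1, p2 = io.write_spikes_tsv(sunits, out / "sim_spikes.tsv", out / "sim_units.tsv")
            record(p1)
            record(p2)
            truth_path = out / "sim_spikes.truth.json"
            truth_path.write_text(json.dumps({
                "rate_per_unit": struth.rate_per_unit,
                "depth_per_unit": struth.depth_per_unit,
                "contaminated_flags": struth.contaminated_flags,
                "seed": struth.seed,
            }, default=_json_default, sort_keys=True))
            record(truth_path)
        if "lfp" in sim:
            lrec, ltruth = synthdata.gen_lfp(**sim["lfp"], seed=seed)
            artifacts["lfp_recording"] = lrec
            p = io.write_lfp_binary(lrec, out / "sim_lfp.f4")
            record(p)
            record(p.with_suffix(p.suffix + ".json"))
            truth_path = out / "sim_lfp.truth.json"
            truth_path.write_text(json.dumps({
                "band_power_targets": ltruth.band_power_targets,
                "n_channels": ltruth.n_channels,
                "common_offset_amplitude": ltruth.common_offset_amplitude,
                "seed": ltruth.seed,
            }, default=_json_default, sort_keys=True))
            record(truth_path)
        if "proteome" in sim:
            table, ptruth = synthdata.gen_proteome(**sim["proteome"], seed=seed)
            artifacts["abundance_table"] = table
            artifacts["proteome_truth"] = ptruth
            p1, p2 = io.write_abundance_tsv(
                table, out / "sim_abundance.tsv", out / "sim_samples.tsv"
            )
            record(p1)
            record(p2)
            truth_path = out / "sim_proteome.truth.json"
            truth_path.write_text(json.dumps({
                "de_flags": ptruth.de_flags,
                "true_log2fc": ptruth.true_log2fc,
                "ecm_labels": ptruth.ecm_labels,
                "group_sizes": ptruth.group_sizes,
                "seed": ptruth.seed,
            }, default=_json_default, sort_keys=True))
            record(truth_path)
        report["stages"]["simulate"] = stage

    if "calcium" in config and config["calcium"] is not None:
        params = dict(config["calcium"])
        source = params.pop("input", None)
        if source:
            path = Path(source)
            if not path.exists():
                raise FileNotFoundError(f"calcium stage: input {path} does not exist")
            rec = (io.read_recording_h5(path) if path.suffix in (".h5", ".hdf5")
                   else io.read_recording_csv(path))
        elif "calcium_recording" in artifacts:
            rec = artifacts["calcium_recording"]
        else:
            raise ConfigError("calcium stage needs an 'input' path or a simulate.calcium block")
        summaries, excluded = calcium.analyze_recording(rec, **params)
        per_animal, pooled = calcium.summarize_animals({rec.animal_id or "animal": summaries})
        record(io.write_events_tsv(summaries, rec.fs, out / "calcium_events.tsv"))
        record(io.write_summary_tsv(summaries, out / "calcium_summary.tsv"))
        report["stages"]["calcium"] = {
            "parameters": params,
            "n_rois": len(summaries),
            "n_excluded": len(excluded),
            "per_animal": per_animal,
        }

    if "units" in config and config["units"] is not None:
        params = dict(config["units"])
        spikes_path = params.pop("spikes", None)
        units_path = params.pop("units", None)
        duration = params.pop("duration_s", 600.0)
        if spikes_path:
            for p in (spikes_path, units_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"units stage: input {p} does not exist")
            sunits = io.read_spikes_tsv(spikes_path, units_path)
        elif "spike_units" in artifacts:
            sunits = artifacts["spike_units"]
        else:
            raise ConfigError("units stage needs spike inputs or a simulate.spikes block")
        table = units.unit_table(
            sunits, duration,
            bin_s=params.get("bin_s", 1.0),
            refractory_ms=params.get("refractory_ms", 2.0),
            max_fraction=params.get("max_violation", 0.01),
        )
        table.to_csv(out / "unit_table.tsv", sep="\t", index=False)
        record(out / "unit_table.tsv")
        report["stages"]["units"] = {
            "parameters": params,
            "n_units": int(len(table)),
            "n_pass": int(table["passes"].sum()) if len(table) else 0,
            "depth_bins": units.depth_bin_summary(table),
        }

    if "lfp" in config and config["lfp"] is not None:
        params = dict(config["lfp"])
        source = params.pop("input", None)
        if source:
            path = Path(source)
            if not path.exists():
                raise FileNotFoundError(f"lfp stage: input {path} does not exist")
            lrec = io.read_lfp_binary(path)
        elif "lfp_recording" in artifacts:
            lrec = artifacts["lfp_recording"]
        else:
            raise ConfigError("lfp stage needs an 'input' path or a simulate.lfp block")
        bp = lfp.analyze_lfp(lrec, **params)
        bp_path = out / "band_power.tsv"
        with open(bp_path, "w") as fh:
            fh.write("band\tmean_psd\tintegrated_power\n")
            for name, val in bp.as_dict().items():
                fh.write(f"{name}\t{val:.10g}\t{bp.integrated.get(name, float('nan')):.10g}\n")
        record(bp_path)
        report["stages"]["lfp"] = {"parameters": params, "band_power": bp.as_dict(),
                                   "integrated_power": bp.integrated}

    if "proteomics" in config and config["proteomics"] is not None:
        params = dict(config["proteomics"])
        abundance = params.pop("abundance", None)
        samples = params.pop("samples", None)
        gene_sets = params.pop("gene_sets", None)
        regulators = params.pop("regulators", None)
        if abundance:
            for p in (abundance, samples):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"proteomics stage: input {p} does not exist")
            table = io.read_abundance_tsv(
                abundance, samples, min_valid_per_group=params.pop("min_valid_per_group", 3)
            )
        elif "abundance_table" in artifacts:
            params.pop("min_valid_per_group", None)
            table = artifacts["abundance_table"]
        else:
            raise ConfigError("proteomics stage needs abundance inputs or a simulate.proteome block")
        group_a = params.pop("group_a", None)
        group_b = params.pop("group_b", None)
        if group_a is None or group_b is None:
            labels = list(dict.fromkeys(table.groups.loc[list(table.data.columns)]))
            group_a = group_a or labels[0]
            group_b = group_b or labels[1]
        alpha = params.pop("alpha", 0.05)
        fc_cut = params.pop("fc_cut", 1.5)
        de = proteomics.welch_de(table, group_a, group_b, alpha=alpha)
        de.to_csv(out / "differential.tsv", sep="\t")
        record(out / "differential.tsv")
        stage = {
            "parameters": {"group_a": group_a, "group_b": group_b, "alpha": alpha,
                           "fc_cut": fc_cut},
            "n_tested": int(len(de)),
            "n_significant": int(de["significant"].sum()),
            "n_up": int((de["significant"] & (de["log2fc"] > 0)).sum()),
            "n_down": int((de["significant"] & (de["log2fc"] < 0)).sum()),
        }
        if gene_sets:
            collection = proteomics.GeneSetCollection.from_gmt(gene_sets, universe=de.index)
            up = de.index[de["significant"] & (de["log2fc"] > 0)]
            if len(up):
                enr = proteomics.enrich_sets(up, collection)
                enr.to_csv(out / "enrichment_up.tsv", sep="\t", index=False)
                record(out / "enrichment_up.tsv")
                stage["top_up_set"] = str(enr.iloc[0]["set"]) if len(enr) else None
        if regulators:
            network = proteomics.RegulatorNetwork.from_gmt(regulators)
            regs = proteomics.regulator_enrichment(de, network, p_cut=0.05, fc_cut=fc_cut)
            regs.to_csv(out / "regulators.tsv", sep="\t", index=False)
            record(out / "regulators.tsv")
            stage["top_regulator"] = str(regs.iloc[0]["regulator"]) if len(regs) else None
        report["stages"]["proteomics"] = stage

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, default=_json_default, sort_keys=True, indent=1))
    logger.info("pipeline finished: %d stage(s), report at %s", len(report["stages"]), report_path)
    return report


# ---------------------------------------------------------------------------
# two-genotype synthetic scenario
# ---------------------------------------------------------------------------

def run_genotype_scenario(
    seed: int = 0,
    n_animals: int = 3,
    n_rois_per_animal: int = 250,
    calcium_duration_s: float = 300.0,
    frac_hyper_mutant: float = 0.15,
    frac_hyper_control: float = 0.02,
    snr: float = 5.0,
    n_units_per_group: int = 150,
    lfp_duration_s: float = 400.0,
    n_proteins: int = 2000,
) -> dict:
    """Full synthetic two-genotype experiment and its directional read-out.

    The mutant-like group has more hyperactive superficial neurons, equal
    layer-5 firing rates, reduced slow-band and raised gamma-band LFP power,
    and an up-shifted ECM protein module; the control group is the baseline.
    Returns per-group summaries and boolean direction checks:

    ``hyperactive_up`` - mean percent hyperactive higher in the mutant group;
    ``layer5_rates_similar`` - |median log10 rate difference| < 0.1;
    ``slow_power_down``, ``mid_gamma_up``, ``high_gamma_up`` - band power
    directions; ``ecm_top_up_enriched`` - the ECM set ranks first among
    up-enriched sets.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 * n_animals + 4)]
    si = iter(seeds)

    # --- calcium: superficial-layer hyperactivity -------------------------
    groups: dict[str, dict] = {}
    for name, frac in (("control", frac_hyper_control), ("mutant", frac_hyper_mutant)):
        by_animal = {}
        for a in range(n_animals):
            rec, _ = synthdata.gen_calcium(
                n_rois=n_rois_per_animal,
                duration_s=calcium_duration_s,
                frac_hyper=frac,
                rate_hyper=4.0,
                rate_base=0.5,
                snr=snr,
                animal_id=f"{name}{a}",
                genotype=name,
                layer="superficial",
                seed=next(si),
            )
            summaries, _ = calcium.analyze_recording(rec)
            by_animal[rec.animal_id] = summaries
        per_animal, pooled = calcium.summarize_animals(by_animal)
        groups[name] = {
            "per_animal": per_animal,
            "mean_percent_hyperactive": float(
                np.mean([v["percent_hyperactive"] for v in per_animal.values()])
            ),
            "pooled_rates": pooled,
        }

    # --- units: layer-5 rates drawn from the same distribution ------------
    layer5_median: dict[str, float] = {}
    for name in ("control", "mutant"):
        sunits, _ = synthdata.gen_spikes(
            n_units=n_units_per_group,
            duration_s=600.0,
            rate_log_mean=0.0,
            rate_log_sd=0.4,
            depth_range=(550.0, 800.0),
            frac_contaminated=0.1,
            seed=next(si),
        )
        table = units.unit_table(sunits, 600.0)
        summary = units.depth_bin_summary(table)
        layer5_median[name] = summary["layer5"]["log10_rate_median"]
        groups[name]["layer5"] = summary["layer5"]

    # --- LFP: slow power halved, gamma doubled in the mutant --------------
    lfp_targets = {
        "control": {"slow": 1.0, "mid_gamma": 0.05, "high_gamma": 0.02},
        "mutant": {"slow": 0.5, "mid_gamma": 0.10, "high_gamma": 0.04},
    }
    for name in ("control", "mutant"):
        band_means: dict[str, list[float]] = {"slow": [], "mid_gamma": [], "high_gamma": []}
        for _a in range(n_animals):
            lrec, _ = synthdata.gen_lfp(
                duration_s=lfp_duration_s,
                n_channels=4,
                band_power_targets=lfp_targets[name],
                common_offset_amplitude=0.5,
                seed=next(si),
            )
            bp = lfp.analyze_lfp(lrec)
            for band in band_means:
                band_means[band].append(bp.as_dict()[band])
        groups[name]["band_power"] = {b: float(np.mean(v)) for b, v in band_means.items()}

    # --- proteomics: ECM module up in the mutant ---------------------------
    prot_seed = next(si)
    table, ptruth = synthdata.gen_proteome(
        n_proteins=n_proteins,
        group_sizes={"WT": 4, "MUT": 5},
        frac_de=0.1,
        lfc_location=1.5,
        up_fraction=0.8,
        frac_ecm=0.1,
        ecm_de_odds=8.0,
        seed=prot_seed,
    )
    de = proteomics.welch_de(table, "WT", "MUT")
    gene_sets = synthdata.make_gene_sets(ptruth, seed=prot_seed)
    up_ids = de.index[de["significant"] & (de["log2fc"] > 0)]
    enr = proteomics.enrich_sets(up_ids, gene_sets)
    network = synthdata.make_regulator_network(ptruth, seed=prot_seed)
    regs = proteomics.regulator_enrichment(de, network)
    groups["proteomics"] = {
        "n_significant": int(de["significant"].sum()),
        "n_up": int(len(up_ids)),
        "top_up_set": str(enr.iloc[0]["set"]),
        "top_regulator": str(regs.iloc[0]["regulator"]),
        "top_regulator_z": float(regs.iloc[0]["z"]),
    }

    checks = {
        "hyperactive_up": groups["mutant"]["mean_percent_hyperactive"]
        > groups["control"]["mean_percent_hyperactive"],
        "layer5_rates_similar": abs(layer5_median["mutant"] - layer5_median["control"]) < 0.1,
        "slow_power_down": groups["mutant"]["band_power"]["slow"]
        < groups["control"]["band_power"]["slow"],
        "mid_gamma_up": groups["mutant"]["band_power"]["mid_gamma"]
        > groups["control"]["band_power"]["mid_gamma"],
        "high_gamma_up": groups["mutant"]["band_power"]["high_gamma"]
        > groups["control"]["band_power"]["high_gamma"],
        "ecm_top_up_enriched": groups["proteomics"]["top_up_set"] == "ECM",
    }
    return {"groups": groups, "checks": checks, "seed": seed}
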