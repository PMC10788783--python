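"""Config-driven pipeline orchestration.

One declarative YAML file is the single source of truth; the command line
only selects the subcommand, the config path and the output directory, so
the recorded provenance (config hash + global seed) fully determines every
artifact.  Stages write small text artifacts (EDF signals, TSV events, JSON
metadata, tidy CSV tables) and each stage reads only its predecessors'
outputs, so stages are individually re-runnable.

Stage seeds are derived deterministically from the global seed, the stage
name and the participant index.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__, erpperm, impstats, pairing, preprocess, simmetrics, synthgen
from .ioformats import (
    EventList,
    Recording,
    attach_layout,
    read_edf,
    read_events,
    read_impedance,
    read_layout,
    write_edf,
    write_events,
    write_impedance,
    write_layout,
)

log = logging.getLogger("drybench")

STAGES = ("generate", "preprocess", "analyze", "erp", "permute", "impedance", "report")


class StageError(RuntimeError):
    """A stage failed; the message names the stage and the offending file."""


def stage_seed(global_seed: int, stage: str, participant: int = 0) -> int:
    """Deterministic per-stage, per-participant seed below 2**31."""
    h = zlib.crc32(stage.encode()) & 0xFFFFFFFF
    return (global_seed * 2654435761 + h * 97 + participant) % (2**31)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_participants": 3,
    "generator": {"fs": 2000.0, "duration_s": 600.0},
    "layout": {"pitch_mm": 6.0, "rows": 4, "cols": 4,
               "reference_offsets_mm": [[-20.0, 0.0], [-20.0, 20.0]]},
    "preprocess": {
        "transition_bw": 1.0,
        "channel_rejection": {"window_s": 5.0, "corr_threshold": 0.8,
                              "bad_fraction": 0.5, "n_neighbors": 4},
        "artifact": {"window_s": 1.0, "z_threshold": 20.0},
        "regular_epoch_s": 2.0,
        "cued_window_s": [-0.2, 1.0],
        "cued_baseline_s": [-0.2, 0.0],
    },
    "spectral": {"f_range": [2.0, 35.0], "resolution_hz": 1.0, "overlap": 0.5},
    "permutation": {"n_permutations": 1000},
    "impedance": {"n_dry": 200, "n_gelled": 10},
}


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return dict(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_update(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]


def _participants(config: dict) -> list[str]:
    return [f"p{i:02d}" for i in range(int(config["n_participants"]))]


def _spectral_params(config: dict) -> simmetrics.SpectralParams:
    sp = config["spectral"]
    return simmetrics.SpectralParams(
        overlap=float(sp["overlap"]),
        f_range=tuple(sp["f_range"]),
        resolution_hz=float(sp["resolution_hz"]),
    )


def _generator_config(config: dict, seed: int) -> synthgen.GeneratorConfig:
    gen = dict(config["generator"])
    kwargs: dict = {"seed": seed}
    if "fs" in gen:
        kwargs["fs"] = float(gen["fs"])
    if "duration_s" in gen:
        kwargs["duration_s"] = float(gen["duration_s"])
    if "bands" in gen:
        kwargs["bands"] = tuple(
            synthgen.BandSpec(b["name"], b["f_lo"], b["f_hi"],
                              b["source_rms_uv"], b["spatial_scale_mm"])
            for b in gen["bands"]
        )
    if "burst" in gen:
        kwargs["burst"] = synthgen.BurstSpec(**gen["burst"]) if gen["burst"] else None
    if "noise" in gen:
        kwargs["noise"] = synthgen.NoiseSpec(**gen["noise"])
    if "trial" in gen:
        kwargs["trial"] = synthgen.TrialSpec(**gen["trial"])
    if "impedance_model" in gen:
        kwargs["impedance"] = synthgen.ImpedanceModel(**gen["impedance_model"])
    return synthgen.GeneratorConfig(**kwargs)


def _layout(config: dict) -> "synthgen.ElectrodeLayout":
    lay = config["layout"]
    return synthgen.gen_layout(
        pitch_mm=float(lay["pitch_mm"]),
        rows=int(lay["rows"]),
        cols=int(lay["cols"]),
        reference_offsets_mm=[tuple(p) for p in lay["reference_offsets_mm"]],
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_generate(config: dict, out: Path) -> None:
    layout = _layout(config)
    for i, pid in enumerate(_participants(config)):
        pdir = out / pid
        pdir.mkdir(parents=True, exist_ok=True)
        gc = _generator_config(config, stage_seed(config["seed"], "generate", i))
        synth = synthgen.gen_recording(gc, layout)
        peak = float(np.max(np.abs(synth.recording.samples)))
        phys = max(1000.0, float(np.ceil(peak / 100.0) * 100 + 100))
        write_edf(synth.recording, pdir / "recording.edf", physical_range_uv=phys)
        write_events(synth.events, pdir / "events.tsv")
        write_layout(
            synthgen.ElectrodeLayout(synth.recording.channels), pdir / "layout.json"
        )
        truth = {
            "effective_corr": {k: v.tolist() for k, v in synth.effective_corr.items()},
            "kernels": {k: v.tolist() for k, v in synth.kernels.items()},
            "noise_variance_uv2": synth.noise_variance_uv2.tolist(),
            "erp_template": synth.erp_template.tolist(),
            "erp_times_s": synth.erp_times.tolist(),
            "channel_order": synth.recording.labels,
        }
        with open(pdir / "truth.json", "w") as fh:
            json.dump(truth, fh)
        log.info("generate %s: %d events, peak %.1f µV", pid, len(synth.events), peak)
    # impedance study sample (separate draw, mirroring the dedicated sessions)
    imp = config["impedance"]
    gc0 = _generator_config(config, 0)
    rng = np.random.default_rng(stage_seed(config["seed"], "impedance-sample"))
    dry = synthgen.gen_impedance(gc0.impedance, int(imp["n_dry"]), "dry", rng)
    gel = synthgen.gen_impedance(gc0.impedance, int(imp["n_gelled"]), "gelled", rng)
    table = pd.DataFrame(
        {
            "label": [f"MX{i:03d}" for i in range(len(dry))] + [f"AG{i:02d}" for i in range(len(gel))],
            "type": ["dry"] * len(dry) + ["gelled"] * len(gel),
            # store raw kOhm so the analysis exercises area normalization
            "kohm": np.concatenate([dry / (np.pi * (3.0 / 20.0) ** 2),
                                    gel / (np.pi * (10.0 / 20.0) ** 2)]),
            "diameter_mm": [3.0] * len(dry) + [10.0] * len(gel),
            "timepoint": "t0",
        }
    )
    write_impedance(table, out / "impedance.csv")


def _load_participant(out: Path, pid: str) -> tuple[Recording, EventList]:
    pdir = out / pid
    for fname in ("recording.edf", "events.tsv", "layout.json"):
        if not (pdir / fname).exists():
            raise StageError(
                f"stage needs {pdir / fname}; run the 'generate' stage first"
            )
    try:
        rec = read_edf(pdir / "recording.edf")
        layout = read_layout(pdir / "layout.json")
        events = read_events(pdir / "events.tsv")
    except Exception as exc:
        raise StageError(f"reading inputs for {pid} failed: {exc}") from exc
    return attach_layout(rec, layout), events


def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(np.int8), [0]])))
    for a, b in zip(idx[::2], idx[1::2]):
        runs.append([int(a), int(b)])
    return runs


def _runs_to_mask(runs: list, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for a, b in runs:
        mask[a:b] = True
    return mask


def run_preprocess(config: dict, out: Path) -> None:
    pp = config["preprocess"]
    for pid in _participants(config):
        rec, _ = _load_participant(out, pid)
        broadband = preprocess.apply_filter(
            rec, preprocess.design_filter(*preprocess.DEFAULT_BANDS["Broadband"],
                                          rec.fs, pp["transition_bw"])
        )
        rejected = preprocess.reject_channels_iterative(
            broadband, **{k: v for k, v in pp["channel_rejection"].items()}
        )
        for lab in rejected:
            idx = broadband.channel_index(lab)
            broadband.channels[idx].status = "rejected"
        mask = preprocess.reject_artifact_windows(broadband, **pp["artifact"])
        result = {
            "rejected_channels": sorted(rejected),
            "retained_runs": _mask_to_runs(mask),
            "n_times": rec.n_times,
            "retained_fraction": float(mask.mean()),
        }
        with open(out / pid / "preprocess.json", "w") as fh:
            json.dump(result, fh)
        log.info("preprocess %s: %d channels rejected, %.1f%% samples retained",
                 pid, len(rejected), 100 * mask.mean())


def _load_preprocessed(config: dict, out: Path, pid: str) -> tuple[Recording, EventList, dict]:
    rec, events = _load_participant(out, pid)
    ppath = out / pid / "preprocess.json"
    if not ppath.exists():
        raise StageError(f"stage needs {ppath}; run the 'preprocess' stage first")
    try:
        with open(ppath) as fh:
            pp = json.load(fh)
        rec.mask = _runs_to_mask(pp["retained_runs"], rec.n_times)
    except (json.JSONDecodeError, KeyError) as exc:
        raise StageError(f"corrupt intermediate file {ppath}: {exc}") from exc
    for lab in pp["rejected_channels"]:
        rec.channels[rec.channel_index(lab)].status = "rejected"
    return rec, events, pp


def _roles_and_pairs(rec: Recording):
    layout = synthgen.ElectrodeLayout(rec.channels)
    rejected = {ch.label for ch in rec.channels if ch.status == "rejected"}
    roles = pairing.assign_roles(layout, rejected=rejected)
    return roles, pairing.build_pairs(layout, roles)


def run_analyze(config: dict, out: Path) -> None:
    pp = config["preprocess"]
    params = _spectral_params(config)
    adir = out / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    corr_rows, rms_rows, psd_rows, msc_rows, stab_rows, pair_rows = [], [], [], [], [], []
    for pid in _participants(config):
        rec, _, _ = _load_preprocessed(config, out, pid)
        roles, pairs = _roles_and_pairs(rec)
        roles.to_json(out / pid / "roles.json")
        variants = preprocess.make_band_variants(rec, transition_bw=pp["transition_bw"])
        preprocess.propagate_rejections(rec, list(variants.values()))
        for _, row in pairs.to_frame().iterrows():
            pair_rows.append({"participant": pid, **row})
        # timeseries correlations: concatenated retained samples, per band
        for band, brec in variants.items():
            for name, a, b, _d in pairs.pairs:
                rho = simmetrics.band_correlation(
                    brec.get(a)[rec.mask], brec.get(b)[rec.mask]
                )
                corr_rows.append(
                    {"participant": pid, "pair": name, "band": band, "value": rho}
                )
        # regular epochs: RMS on broadband, spectra on unfiltered
        ep_broad = preprocess.extract_regular_epochs(
            variants["Broadband"], pp["regular_epoch_s"]
        )
        ep_raw = preprocess.extract_regular_epochs(rec, pp["regular_epoch_s"])
        for role in ("AG", "AG2", "MX-Near", "MX-Neighbor", "MX-Far",
                     "MX-Q1", "MX-Q2", "MX-Q3", "MX-Q4"):
            if role not in roles:
                continue
            _, mean_rms = simmetrics.rms_amplitude(ep_broad, roles[role])
            rms_rows.append(
                {"participant": pid, "pair": role, "band": "Broadband", "value": mean_rms}
            )
            freqs, _, mean_db = simmetrics.welch_psd(ep_raw, roles[role], params)
            for f, v in zip(freqs, mean_db):
                psd_rows.append(
                    {"participant": pid, "pair": role, "band": f"{f:g}Hz", "value": v}
                )
        for name, a, b, _d in pairs.pairs:
            freqs, coh = simmetrics.msc(ep_raw, (a, b), params, mode="epoch")
            for f, v in zip(freqs, coh):
                msc_rows.append(
                    {"participant": pid, "pair": name, "band": f"{f:g}Hz", "value": v}
                )
            stab_rows.append(
                {
                    "participant": pid, "pair": name, "band": "all",
                    "value": simmetrics.split_half_stability(ep_raw, (a, b), params),
                }
            )
        log.info("analyze %s: %d regular epochs", pid, ep_raw.n_epochs)
    for fname, rows in (
        ("pairs.csv", pair_rows),
        ("band_correlations.csv", corr_rows),
        ("rms.csv", rms_rows),
        ("psd.csv", psd_rows),
        ("msc.csv", msc_rows),
        ("split_half.csv", stab_rows),
    ):
        frame = pd.DataFrame(rows)
        frame.to_csv(adir / fname, index=False)
        if fname != "pairs.csv" and len(frame):
            simmetrics.grand_average(frame).to_csv(
                adir / fname.replace(".csv", "_grand.csv"), index=False
            )


def run_erp(config: dict, out: Path) -> None:
    pp = config["preprocess"]
    adir = out / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    wave_rows, corr_rows, comp_rows = [], [], []
    for pid in _participants(config):
        rec, events, _ = _load_preprocessed(config, out, pid)
        roles, pairs = _roles_and_pairs(rec)
        broadband = preprocess.apply_filter(
            rec, preprocess.design_filter(*preprocess.DEFAULT_BANDS["Broadband"],
                                          rec.fs, pp["transition_bw"])
        )
        broadband.mask = rec.mask.copy()
        cued = preprocess.extract_cued_epochs(
            broadband, events.select("cue"),
            tuple(pp["cued_window_s"]), tuple(pp["cued_baseline_s"]),
        )
        if cued.n_epochs == 0:
            log.warning("erp %s: no clean cued epochs; skipping", pid)
            continue
        erps: dict[str, erpperm.Erp] = {}
        for role in ("AG", "AG2", "MX-Near", "MX-Neighbor", "MX-Q1", "MX-Q2", "MX-Q3", "MX-Q4"):
            if role not in roles:
                continue
            erp = erpperm.compute_erp(cued, roles[role])
            erps[role] = erp
            for t, v in zip(erp.times_s, erp.waveform):
                wave_rows.append({"participant": pid, "role": role, "time_s": t, "uv": v})
            for cname, (lat, amp) in erpperm.detect_components(erp).items():
                comp_rows.append(
                    {"participant": pid, "role": role, "component": cname,
                     "latency_s": lat, "amplitude_uv": amp}
                )
        erp_pairs = [("AG", "AG2"), ("AG", "MX-Near"), ("MX-Near", "MX-Neighbor")]
        for ra, rb in erp_pairs:
            if ra in erps and rb in erps:
                corr_rows.append(
                    {"participant": pid, "pair": f"{ra}:{rb}", "band": "Broadband",
                     "value": erpperm.erp_correlation(erps[ra], erps[rb])}
                )
        # combined corner comparison: both corner pairs share one distance
        corner = [
            erpperm.erp_correlation(erps[a], erps[b])
            for a, b in (("MX-Q1", "MX-Q3"), ("MX-Q2", "MX-Q4"))
            if a in erps and b in erps
        ]
        if corner:
            corr_rows.append(
                {"participant": pid, "pair": "MX-Corner1:MX-Corner2",
                 "band": "Broadband", "value": float(np.mean(corner))}
            )
        log.info("erp %s: %d cued epochs", pid, cued.n_epochs)
    pd.DataFrame(wave_rows).to_csv(adir / "erp_waveforms.csv", index=False)
    pd.DataFrame(comp_rows).to_csv(adir / "erp_components.csv", index=False)
    frame = pd.DataFrame(corr_rows)
    frame.to_csv(adir / "erp_correlations.csv", index=False)
    if len(frame):
        simmetrics.grand_average(frame).to_csv(adir / "erp_correlations_grand.csv", index=False)


def run_permute(config: dict, out: Path) -> None:
    pp = config["preprocess"]
    params = _spectral_params(config)
    adir = out / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    all_rows, summary_rows = [], []
    for i, pid in enumerate(_participants(config)):
        rec, events, _ = _load_preprocessed(config, out, pid)
        roles, _ = _roles_and_pairs(rec)
        broadband = preprocess.apply_filter(
            rec, preprocess.design_filter(*preprocess.DEFAULT_BANDS["Broadband"],
                                          rec.fs, pp["transition_bw"])
        )
        broadband.mask = rec.mask.copy()
        cued = preprocess.extract_cued_epochs(
            broadband, events.select("cue"),
            tuple(pp["cued_window_s"]), tuple(pp["cued_baseline_s"]),
        )
        if cued.n_epochs < 3:
            log.warning("permute %s: fewer than 3 clean cued epochs; skipping", pid)
            continue
        result = erpperm.permute_and_score(
            cued, (roles["AG"], roles["MX-Near"]),
            n_permutations=int(config["permutation"]["n_permutations"]),
            seed=stage_seed(config["seed"], "permute", i),
            params=params,
        )
        frame = result.to_frame()
        frame.insert(0, "participant", pid)
        all_rows.append(frame)
        summ = result.summary()
        summ.insert(0, "participant", pid)
        summary_rows.append(summ)
        log.info("permute %s: unshuffled r=%.3f", pid, result.unshuffled_r)
    if all_rows:
        pd.concat(all_rows, ignore_index=True).to_csv(adir / "permutation.csv", index=False)
        pd.concat(summary_rows, ignore_index=True).to_csv(
            adir / "permutation_summary.csv", index=False
        )


def run_impedance(config: dict, out: Path) -> None:
    path = out / "impedance.csv"
    if not path.exists():
        raise StageError(f"stage needs {path}; run the 'generate' stage first")
    adir = out / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    table = read_impedance(path)
    raw = pd.read_csv(path)  # to pick up type/diameter columns
    table["type"] = raw["type"]
    table["diameter_mm"] = raw["diameter_mm"]
    table["kohm_cm2"] = impstats.area_normalize(
        table["kohm"].to_numpy(), table["diameter_mm"].to_numpy()
    )
    rows = []
    kept = {}
    for kind, sub in table.groupby("type"):
        keep = impstats.tukey_outliers(sub["kohm_cm2"].to_numpy())
        vals = sub["kohm_cm2"].to_numpy()[keep]
        kept[kind] = vals
        med, iqr, n = impstats.summarize(vals)
        rows.append({"type": kind, "median_kohm_cm2": med, "iqr_kohm_cm2": iqr,
                     "n": n, "n_rejected": int((~keep).sum())})
    u, p = impstats.mann_whitney(kept["dry"], kept["gelled"])
    summary = pd.DataFrame(rows)
    summary["mann_whitney_u"] = u
    summary["p_value"] = p
    summary.to_csv(adir / "impedance_summary.csv", index=False)
    with open(adir / "impedance_summary.json", "w") as fh:
        json.dump({"rows": rows, "mann_whitney_u": u, "p_value": p}, fh, indent=1)
    log.info("impedance: U=%.0f, p=%.2e", u, p)


def run_report(config: dict, out: Path) -> None:
    adir = out / "analysis"
    rdir = out / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    needed = ["band_correlations_grand.csv", "msc_grand.csv", "rms_grand.csv"]
    for fname in needed:
        if not (adir / fname).exists():
            raise StageError(f"stage needs {adir / fname}; run the 'analyze' stage first")
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "tables": sorted(p.name for p in adir.glob("*.csv")),
    }
    with open(rdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    # headline summary mirroring the result surfaces
    summary: dict = {}
    corr = pd.read_csv(adir / "band_correlations_grand.csv")
    summary["band_correlations"] = {
        f"{r.pair}|{r.band}": round(float(r.value), 4) for r in corr.itertuples()
    }
    rms = pd.read_csv(adir / "rms_grand.csv")
    summary["rms_uv"] = {r.pair: round(float(r.value), 3) for r in rms.itertuples()}
    pfile = adir / "permutation_summary.csv"
    if pfile.exists():
        perm = pd.read_csv(pfile)
        grand = perm.groupby("pair")["mean"].mean()
        summary["permutation_mean_r"] = {k: round(float(v), 4) for k, v in grand.items()}
    ifile = adir / "impedance_summary.json"
    if ifile.exists():
        with open(ifile) as fh:
            summary["impedance"] = json.load(fh)
    with open(rdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)


RUNNERS = {
    "generate": run_generate,
    "preprocess": run_preprocess,
    "analyze": run_analyze,
    "erp": run_erp,
    "permute": run_permute,
    "impedance": run_impedance,
    "report": run_report,
}


def run(stage: str, config: dict, out: str | Path) -> None:
    """Run one stage (or 'all') of the pipeline with a resolved config dict."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    stages = list(RUNNERS) if stage == "all" else [stage]
    for name in stages:
        if name not in RUNNERS:
            raise StageError(f"unknown stage {name!r}; choose from {list(RUNNERS)} or 'all'")
        log.info("=== stage %s ===", name)
        try:
            RUNNERS[name](config, out)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc


@click.command()
@click.argument("stage", type=click.Choice(STAGES + ("all",)))
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML config; defaults are used when omitted.")
@click.option("--out", "out_dir", type=click.Path(), default="drybench_out",
              help="Output directory.")
@click.option("-v", "--verbose", is_flag=True)
def cli(stage: str, config_path: str | None, out_dir: str, verbose: bool) -> None:
    """Dry-vs-gelled EEG benchmarking pipeline."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
    config = load_config(config_path)
    try:
        run(stage, config, out_dir)
    except StageError as exc:
        raise click.ClickException(str(exc)) from exc
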