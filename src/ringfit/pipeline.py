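"""Config-driven orchestration: generate -> correct -> fit -> report.

A :class:`RunConfig` names the assays to run and their generator/fitting
options; :func:`run_pipeline` executes the requested stages in
dependency order, writes every intermediate dataset and fit under the
output directory, and returns a :class:`RunReport` whose numbers are all
traceable to stage output files. All randomness derives from the config
seed, so rerunning an identical config reproduces the report (minus
timestamps, which are therefore not put in it).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


from . import __version__, binding, hdx, io, smfret, stoichiometry, synthgen

log = logging.getLogger(__name__)

KNOWN_ASSAYS = ("titration", "titration_monophasic", "mp_events", "hdx_bimodal", "fret_traces")

_TOP_KEYS = {"seed", "outdir", "assays", "log_level"}
_ASSAY_KEYS = {
    "titration": {"breakpoints", "plateaus", "protein_nM", "n_steps", "max_x",
                  "noise_sd", "dilution_per_step", "photobleach_per_scan",
                  "max_breakpoints", "n_boot", "fit_isotherm"},
    "titration_monophasic": {"breakpoints", "plateaus", "protein_nM", "n_steps",
                             "max_x", "noise_sd", "dilution_per_step",
                             "photobleach_per_scan", "max_breakpoints", "n_boot",
                             "fit_isotherm"},
    "mp_events": {"components", "n_events", "n_components", "monomer_kDa"},
    "hdx_bimodal": {"means_Da", "widths_Da", "f1", "n_draws", "bin_width_Da"},
    "fret_traces": {"state_means", "occupancies", "dwell_mean_frames",
                    "n_traces", "frames_per_trace", "noise_sd", "n_states",
                    "bin_width"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with all defaults materialized."""

    seed: int
    outdir: Path
    assays: dict
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        assays = raw.get("assays") or {}
        if not assays:
            raise ValueError("config must request at least one assay")
        clean = {}
        for name, opts in assays.items():
            if name not in KNOWN_ASSAYS:
                raise ValueError(f"unknown assay {name!r}; known: {KNOWN_ASSAYS}")
            opts = dict(opts or {})
            bad = set(opts) - _ASSAY_KEYS[name]
            if bad:
                raise ValueError(f"unknown keys for assay {name!r}: {sorted(bad)}")
            clean[name] = opts
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "ringfit_out")),
            assays=clean,
            log_level=str(raw.get("log_level", "INFO")),
        )

    def canonical(self) -> str:
        def enc(o):
            if isinstance(o, Path):
                return str(o)
            raise TypeError
        return json.dumps(
            {"seed": self.seed, "outdir": str(self.outdir), "assays": self.assays,
             "log_level": self.log_level},
            sort_keys=True, default=enc,
        )

    def hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)    # name -> {"status", "result"|"error"}
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages.values())

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version, "stages": self.stages,
            "warnings": self.warnings,
        }


def _stage_titration(name: str, opts: dict, seed: int, outdir: Path) -> dict:
    mono = name == "titration_monophasic"
    truth = synthgen.TitrationTruth(
        breakpoints=tuple(opts.get("breakpoints", (55.0,) if mono else (56.0, 158.0))),
        plateaus=tuple(opts.get("plateaus", (0.6,) if mono else (0.45, 0.75))),
        protein_nM=float(opts.get("protein_nM", 50.0)),
    )
    ds = synthgen.gen_titration(
        truth=truth,
        n_steps=int(opts.get("n_steps", 30)),
        max_x=float(opts.get("max_x", 120.0 if mono else 250.0)),
        noise_sd=float(opts.get("noise_sd", 0.02)),
        dilution_per_step=float(opts.get("dilution_per_step", 0.0015)),
        photobleach_per_scan=float(opts.get("photobleach_per_scan", 0.002)),
        seed=seed,
    )
    csv = io.write_titration_csv(ds, outdir / f"{name}.csv")
    series = io.load_titration_csv(csv, protein_nM=truth.protein_nM)
    fit = binding.estimate_site_sizes(
        series,
        max_breakpoints=int(opts.get("max_breakpoints", 2)),
        n_boot=int(opts.get("n_boot", 200)),
        seed=seed,
    )
    result = {
        "data": csv.name,
        "site_sizes": {
            "n_breakpoints": fit.n_breakpoints,
            "breakpoints_nt_per_ring": fit.breakpoints.tolist(),
            "breakpoint_se": fit.breakpoint_se.tolist(),
            "bic": {str(k): v for k, v in fit.bic.items()},
        },
    }
    if opts.get("fit_isotherm", True):
        mf = binding.fit_two_site(series)
        result["isotherm_fit"] = {
            "tq1": mf.params.tq1, "tq2": mf.params.tq2,
            "k1": mf.params.k1, "k2": mf.params.k2,
            "se": mf.se.tolist(), "rss": mf.rss, "converged": mf.converged,
        }
    io.write_json(result, outdir / f"{name}.fit.json")
    return result


def _stage_mp(opts: dict, seed: int, outdir: Path) -> dict:
    comps = opts.get("components", synthgen.DEFAULT_MP_COMPONENTS)
    events = synthgen.gen_mp_events(
        components=comps, n_events=int(opts.get("n_events", 5000)), seed=seed,
    )
    csv = io.write_mp_events_csv(events, outdir / "mp_events.csv",
                                 truth={"components": [list(c) for c in comps]})
    fit = stoichiometry.fit_mixture(
        io.load_mp_events_csv(csv), int(opts.get("n_components", len(comps))), seed=seed,
    )
    dom = fit.dominant
    call = stoichiometry.call_stoichiometry(
        fit.means[dom], float(opts.get("monomer_kDa", 52.4)),
    )
    result = {
        "data": csv.name,
        "mixture": {
            "means_kDa": fit.means.tolist(), "sds_kDa": fit.sds.tolist(),
            "mass_fractions": fit.mass_fractions.tolist(),
            "loglik": fit.loglik, "converged": fit.converged,
        },
        "stoichiometry": {
            "species_mass_kDa": call.species_mass, "monomer_kDa": call.monomer_mass,
            "n_subunits": call.n_subunits, "residual_fraction": call.residual_fraction,
        },
    }
    io.write_json(result, outdir / "mp_events.fit.json")
    return result


def _stage_hdx(opts: dict, seed: int, outdir: Path) -> dict:
    ds = synthgen.gen_hdx_bimodal(
        means_Da=tuple(opts.get("means_Da", (8.0, 11.0))),
        widths_Da=tuple(opts.get("widths_Da", (0.6, 0.6))),
        f1=float(opts.get("f1", 0.30)),
        n_draws=int(opts.get("n_draws", 1000)),
        bin_width_Da=float(opts.get("bin_width_Da", 0.25)),
        seed=seed,
    )
    csv = io.write_hdx_bimodal_csv(ds, outdir / "hdx_bimodal.csv")
    x, y = io.load_hdx_bimodal_csv(csv)
    fit = hdx.fit_bimodal(x, y, seed=seed)
    result = {
        "data": csv.name,
        "bimodal": {
            "n_populations": fit.n_populations,
            "means_Da": fit.means.tolist(), "widths_Da": fit.widths.tolist(),
            "f1": fit.f1, "unidentifiable": fit.unidentifiable,
            "bic": {str(k): v for k, v in fit.bic.items()},
        },
    }
    io.write_json(result, outdir / "hdx_bimodal.fit.json")
    return result


def _stage_fret(opts: dict, seed: int, outdir: Path) -> dict:
    truth = synthgen.FretTruth(
        state_means=tuple(opts.get("state_means", (0.2, 0.4, 0.6, 0.8))),
        occupancies=tuple(opts.get("occupancies", (0.70, 0.15, 0.10, 0.05))),
        dwell_mean_frames=float(opts.get("dwell_mean_frames", 20.0)),
    )
    traces = synthgen.gen_fret_traces(
        truth=truth,
        n_traces=int(opts.get("n_traces", 20)),
        frames_per_trace=int(opts.get("frames_per_trace", 300)),
        noise_sd=float(opts.get("noise_sd", 30.0)),
        seed=seed,
    )
    manifest = io.write_fret_traces(traces, outdir / "fret", stem="trace")
    loaded = io.load_fret_traces(manifest)
    hist = smfret.state_histogram(loaded, bin_width=float(opts.get("bin_width", 0.05)))
    n_states = opts.get("n_states", len(truth.state_means))
    model = smfret.segment_states(loaded, K=None if n_states is None else int(n_states),
                                  seed=seed)
    dwells = smfret.dwell_table(model)
    result = {
        "data": manifest.name,
        "histogram": {"mode": hist["mode"], "n_frames": hist["n_frames"],
                      "counts": hist["counts"].tolist()},
        "states": {
            "n_states": model.n_states, "means": model.means.tolist(),
            "sds": model.sds.tolist(), "occupancies": model.occupancies.tolist(),
            "converged": model.converged,
        },
        "n_dwells": len(dwells),
    }
    io.write_json(result, outdir / "fret.fit.json")
    return result


_STAGE_ORDER = ("titration", "titration_monophasic", "mp_events", "hdx_bimodal", "fret_traces")


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every requested assay stage; see module docstring."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), seed=config.seed, version=__version__)
    # fixed per-stage seed offsets keep stages independent of each other
    offsets = {name: i + 1 for i, name in enumerate(_STAGE_ORDER)}
    for name in _STAGE_ORDER:
        if name not in config.assays:
            continue
        opts = config.assays[name]
        seed = config.seed * 10 + offsets[name]
        log.info("stage %s (seed %d, config %s)", name, seed, report.config_hash)
        try:
            if name in ("titration", "titration_monophasic"):
                result = _stage_titration(name, opts, seed, outdir)
            elif name == "mp_events":
                result = _stage_mp(opts, seed, outdir)
            elif name == "hdx_bimodal":
                result = _stage_hdx(opts, seed, outdir)
            else:
                result = _stage_fret(opts, seed, outdir)
            report.stages[name] = {"status": "ok", "result": result}
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            log.error("stage %s failed: %s", name, exc)
            report.stages[name] = {"status": "failed", "error": str(exc)}
    io.write_json(report.to_dict(), outdir / "report.json")
    return report
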