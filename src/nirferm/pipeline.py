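"""End-to-end pipeline: simulate/load -> preprocess -> model -> select -> compare.

Configuration is a plain nested mapping (YAML on disk) so it round-trips
through serialization unchanged; every stochastic stage must carry an
explicit seed, validated before any computation starts.  Each run writes all
intermediate tables, a copy of the resolved configuration and a log of the
seeds used, so a run can be reproduced byte-for-byte from its output
directory alone.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    JoinedDataset,
    ReferenceTable,
    SpectrumSet,
    join_dataset,
    read_reference,
    read_spectra,
    write_reference,
    write_spectra,
)
from .evaluation import CVReport, compare_models, plsr_recipe, run_repeated_kfold
from .plsr import compute_vip, fit_plsr
from .preprocessing import SGFilterSpec, reflectance_to_absorbance, sg_smooth
from .selection import SelectionResult, cafs_select, select_by_beta, select_by_vip
from .simulate import (
    FermentationScenario,
    make_benchmark,
    shrunken_scenario,
    small_scenario,
)

logger = logging.getLogger(__name__)

_PRESETS = {
    "default": FermentationScenario,
    "small": small_scenario,
    "shrunken": shrunken_scenario,
}

DEFAULT_CONFIG: dict = {
    "output_dir": "nirferm_run",
    "responses": ["pH", "TSS"],
    "simulate": {"preset": "small", "seed": 0, "overrides": {}},
    "input": None,
    "preprocess": {"to_absorbance": True, "sg_poly_order": 2, "sg_half_window": 1},
    "plsr": {"n_components": 8, "max_components": 15},
    "selection": {
        "methods": ["beta", "vip", "cafs"],
        "beta": {"n_keep": 15},
        "vip": {"threshold": 1.0},
        "cafs": {
            "strength": 2,
            "band_count": 50,
            "n_final": 30,
            "n_components": 8,
            "cv_folds": 5,
            "seed": 0,
        },
    },
    "cv": {"k": 5, "reps": 30, "base_seed": 0},
}


class ConfigError(ValueError):
    """Raised when a run configuration is incomplete or inconsistent."""


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def resolve_config(config: dict | None = None) -> dict:
    """Fill defaults and validate; returns the fully resolved mapping."""
    resolved = _merge(DEFAULT_CONFIG, config or {})
    validate_config(resolved)
    return resolved


def validate_config(config: dict) -> None:
    """Fail fast — before any computation — on missing seeds or inputs."""
    if config.get("simulate") is None and config.get("input") is None:
        raise ConfigError("either 'simulate' or 'input' must be configured")
    if config.get("simulate") is not None:
        if config["simulate"].get("seed") is None:
            raise ConfigError("simulate stage requires an explicit seed")
        preset = config["simulate"].get("preset", "default")
        if preset not in _PRESETS:
            raise ConfigError(f"unknown scenario preset {preset!r}")
    if config.get("cv", {}).get("base_seed") is None:
        raise ConfigError("cross-validation requires an explicit base_seed")
    methods = config.get("selection", {}).get("methods", [])
    unknown = set(methods) - {"beta", "vip", "cafs"}
    if unknown:
        raise ConfigError(f"unknown selection methods: {sorted(unknown)}")
    if "cafs" in methods and config["selection"]["cafs"].get("seed") is None:
        raise ConfigError("CAFS selection requires an explicit seed")
    for response in config.get("responses", []):
        if response not in ("pH", "TSS"):
            raise ConfigError(f"unknown response {response!r}")


def scenario_from_config(sim_cfg: dict) -> FermentationScenario:
    preset = _PRESETS[sim_cfg.get("preset", "default")]
    overrides = dict(sim_cfg.get("overrides") or {})
    overrides["seed"] = sim_cfg["seed"]
    if preset is FermentationScenario:
        base = FermentationScenario()
    else:
        base = preset()
    valid = {f.name for f in dataclasses.fields(FermentationScenario)}
    bad = set(overrides) - valid
    if bad:
        raise ConfigError(f"unknown scenario overrides: {sorted(bad)}")
    return dataclasses.replace(base, **overrides)


def _selection_to_frame(result: SelectionResult, wavelengths: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": result.indices,
            "wavelength_nm": wavelengths[result.indices],
            "score": result.scores[result.indices],
        }
    )


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the full workflow described by ``config``.

    Returns a mapping with, per response, the comparison table and the
    underlying CV reports; all artifacts are also written to
    ``config["output_dir"]``.
    """
    config = resolve_config(config)
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    log_lines = [f"nirferm {__version__}"]

    # -- stage: acquire data ---------------------------------------------
    try:
        if config["simulate"] is not None:
            scenario = scenario_from_config(config["simulate"])
            benchmark = make_benchmark(scenario)
            spectra = benchmark.spectra
            refs = {"pH": benchmark.ph_ref, "TSS": benchmark.tss_ref}
            write_spectra(spectra, out_dir / "spectra.csv")
            for name, ref in refs.items():
                write_reference(ref, out_dir / f"reference_{name}.csv")
            log_lines.append(f"simulate: seed={scenario.seed} n={spectra.n_samples}")
        else:
            inp = config["input"]
            spectra = read_spectra(inp["spectra"], inp.get("mode", "reflectance"))
            refs = {
                resp: read_reference(inp[f"reference_{resp}"], resp)
                for resp in config["responses"]
            }
            log_lines.append(f"load: {inp['spectra']} n={spectra.n_samples}")
    except Exception as exc:
        raise StageError(f"acquire-data stage failed: {exc}") from exc

    # -- stage: preprocess ------------------------------------------------
    try:
        pp = config["preprocess"]
        if pp.get("to_absorbance", True) and spectra.mode == "reflectance":
            spectra = reflectance_to_absorbance(spectra)
        sg = SGFilterSpec(
            poly_order=pp.get("sg_poly_order", 2),
            half_window=pp.get("sg_half_window", 1),
        )
        spectra = sg_smooth(spectra, sg)
        write_spectra(spectra, out_dir / "preprocessed.csv")
        log_lines.append(
            f"preprocess: absorbance + SG(order={sg.poly_order}, window={sg.window_length})"
        )
    except Exception as exc:
        raise StageError(f"preprocess stage failed: {exc}") from exc

    cv_cfg = config["cv"]
    plsr_cfg = config["plsr"]
    sel_cfg = config["selection"]
    results: dict = {"config": config}

    for response in config["responses"]:
        try:
            joined = join_dataset(spectra, refs[response])
        except Exception as exc:
            raise StageError(f"join stage failed for {response}: {exc}") from exc
        X, y = joined.X, joined.y
        n_comp = plsr_cfg.get("n_components")
        max_comp = plsr_cfg.get("max_components", 15)

        # full-spectrum cross-validation
        full_report = run_repeated_kfold(
            X,
            y,
            plsr_recipe(n_comp, max_components=max_comp),
            k=cv_cfg["k"],
            reps=cv_cfg["reps"],
            base_seed=cv_cfg["base_seed"],
        )
        full_report.to_csv(out_dir / f"full_cv_{response}.csv")
        log_lines.append(
            f"{response}: full CV base_seed={cv_cfg['base_seed']} "
            f"k={cv_cfg['k']} reps={cv_cfg['reps']}"
        )

        # selections on the full dataset
        a_fit = min(n_comp or 8, X.shape[1], X.shape[0] - 1)
        full_model = fit_plsr(X, y, a_fit)
        selections: dict[str, SelectionResult] = {}
        for method in sel_cfg["methods"]:
            try:
                if method == "beta":
                    selections[method] = select_by_beta(
                        full_model, n_keep=sel_cfg["beta"]["n_keep"]
                    )
                elif method == "vip":
                    selections[method] = select_by_vip(
                        compute_vip(full_model), threshold=sel_cfg["vip"]["threshold"]
                    )
                elif method == "cafs":
                    cafs = dict(sel_cfg["cafs"])
                    selections[method] = cafs_select(X, y, **cafs)
            except Exception as exc:
                raise StageError(
                    f"selection stage ({method}) failed for {response}: {exc}"
                ) from exc
            frame = _selection_to_frame(selections[method], spectra.wavelengths)
            frame.to_csv(out_dir / f"selection_{method}_{response}.csv", index=False)
            log_lines.append(
                f"{response}: {method} selected {selections[method].n_selected} wavelengths"
            )

        # optimized-model cross-validation with matched fold seeds
        optimized: dict[str, CVReport] = {}
        for method, sel in selections.items():
            report = run_repeated_kfold(
                X,
                y,
                plsr_recipe(n_comp, max_components=max_comp, indices=sel.indices),
                k=cv_cfg["k"],
                reps=cv_cfg["reps"],
                base_seed=cv_cfg["base_seed"],
            )
            report.to_csv(out_dir / f"optimized_cv_{method}_{response}.csv")
            optimized[method] = report

        table = compare_models(
            full_report,
            optimized,
            n_variables={m: s.n_selected for m, s in selections.items()},
            full_n_variables=X.shape[1],
        )
        table.to_csv(out_dir / f"comparison_{response}.csv", index=False)
        results[response] = {
            "comparison": table,
            "full": full_report,
            "optimized": optimized,
            "selections": selections,
        }

    with open(out_dir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return results
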