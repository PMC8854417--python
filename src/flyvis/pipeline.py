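"""End-to-end study replica: traits -> regimes -> OU models -> contrasts.

A single config drives the whole analysis and writes a deterministic report
bundle: the (derived or loaded) species trait table, every maximum-parsimony
regime painting with its four OU model fits per response trait, the
SAT/NON-SAT contrasts and size-relative correlation matrix, plus a MANIFEST
and a JSON-lines run log.  The interommatidial angle is excluded from OU
fitting by default (it is a deterministic transform of the ommatidium
count) but kept in the descriptive contrasts.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .comparative_stats import group_summary, ols_regression, relative_correlations
from .io_fixtures import (
    RegimeAssignment,
    builtin_fixture,
    read_regimes,
    read_trait_table,
    read_tree,
)
from .morphometrics import DELTA_GAMMA_CONSTANT, aggregate_species
from .ou_adaptation import fit_all_models
from .regimes import enumerate_mp_reconstructions, painting_to_dict

EYE_TRAITS = ("E_area", "OC_diameter", "OM_number", "OM_area")
ANTENNAL_TRAITS = ("A_length", "F_length", "P_length", "ANT_length")
CORRELATION_EYE = ("OM_number", "E_area")
CORRELATION_ANT = ("ANT_length", "A_length", "F_length")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, trait lists and flags for one pipeline run."""

    out_dir: str = "flyvis_out"
    tree: str | None = None
    traits: list[str] = field(default_factory=list)  # species-level tables, joined
    specimens: str | None = None  # per-specimen table; derived then aggregated
    regimes: str | None = None  # None -> packaged fixture
    responses: list[str] = field(
        default_factory=lambda: list(EYE_TRAITS) + list(ANTENNAL_TRAITS)
    )
    include_delta_gamma: bool = False
    log_transform: bool = True
    measurement_error: bool = False
    delta_gamma_constant: float = DELTA_GAMMA_CONSTANT
    contrasts_only: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict.

    Outputs are written under ``config.out_dir``; any stage failure is
    re-raised as :class:`PipelineError` after writing a MANIFEST that marks
    the run incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    manifest = {"complete": False, "stages": [], "outputs": []}
    t0 = time.time()

    def log(event: str, **kw) -> None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"t": round(time.time() - t0, 3), "event": event, **kw}) + "\n")

    log(
        "start",
        version=__version__,
        python=platform.python_version(),
        numpy=np.__version__,
        seed=config.seed,
        flags={
            "log_transform": config.log_transform,
            "measurement_error": config.measurement_error,
            "delta_gamma_constant": config.delta_gamma_constant,
            "contrasts_only": config.contrasts_only,
        },
    )
    report: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                log("error", stage=name, message=str(exc))
                _json_dump(manifest, out / "MANIFEST.json")
                raise PipelineError(name, exc) from exc
            manifest["stages"].append(name)
            log("stage_done", stage=name)

        return deco

    state: dict = {}

    @stage("load_traits")
    def _():
        if config.specimens:
            specimens = read_trait_table(config.specimens, level="specimen")
            table = aggregate_species(
                specimens, delta_gamma_constant=config.delta_gamma_constant
            )
        elif config.traits:
            tables = [read_trait_table(p, level="species") for p in config.traits]
            table = tables[0]
            for t in tables[1:]:
                table = table.join(t)
        else:
            table = builtin_fixture("traits")
        table.to_csv(out / "species_traits.csv")
        manifest["outputs"].append("species_traits.csv")
        state["traits"] = table

    @stage("load_regimes")
    def _():
        regimes = (
            read_regimes(config.regimes) if config.regimes else builtin_fixture("regimes")
        )
        regimes.check_covers(state["traits"].species)
        state["regimes"] = regimes

    @stage("contrasts")
    def _():
        table = state["traits"]
        regimes: RegimeAssignment = state["regimes"]
        contrast_traits = [
            t
            for t in ["H_width", *EYE_TRAITS, "delta_gamma", *ANTENNAL_TRAITS]
            if f"{t}_mean" in table.df.columns
        ]
        contrasts = [group_summary(table, regimes, t).to_dict() for t in contrast_traits]
        block: dict = {"group_contrasts": contrasts}
        if {"H_width_mean", "delta_gamma_mean"} <= set(table.df.columns):
            slope, intercept, r2 = ols_regression(
                table.mean("H_width"), table.mean("delta_gamma")
            )
            block["delta_gamma_vs_H_width_ols"] = {
                "slope": slope,
                "intercept": intercept,
                "R2": r2,
            }
        have = set(t for t in table.traits)
        eye = [t for t in CORRELATION_EYE if t in have]
        ant = [t for t in CORRELATION_ANT if t in have]
        if eye and ant and "H_width" in have:
            corr = relative_correlations(table, eye, ant)
            corr.to_csv(out / "correlations.csv", index=False)
            manifest["outputs"].append("correlations.csv")
            block["relative_correlations"] = corr.to_dict(orient="records")
        _json_dump(block, out / "contrasts.json")
        manifest["outputs"].append("contrasts.json")
        report["contrasts"] = block

    if config.tree and not config.contrasts_only:

        @stage("regime_mapping")
        def _():
            tree = read_tree(config.tree, rescale=True)
            missing = set(tree.tip_labels) ^ set(state["traits"].species)
            if missing:
                raise ValueError(f"tree/trait species mismatch: {sorted(missing)}")
            paintings = enumerate_mp_reconstructions(tree, state["regimes"])
            _json_dump(
                [painting_to_dict(tree, p) for p in paintings], out / "paintings.json"
            )
            manifest["outputs"].append("paintings.json")
            state["tree"] = tree
            state["paintings"] = paintings
            log("paintings", count=len(paintings), n_changes=paintings[0].n_changes)

        @stage("ou_models")
        def _():
            responses = list(config.responses)
            if config.include_delta_gamma and "delta_gamma" not in responses:
                responses.append("delta_gamma")
            blocks = []
            for painting in state["paintings"]:
                for response in responses:
                    tbl = fit_all_models(
                        state["tree"],
                        state["traits"],
                        painting,
                        response,
                        log_transform=config.log_transform,
                        measurement_error=config.measurement_error,
                    )
                    blocks.append(
                        {
                            "reconstruction_index": painting.reconstruction_index,
                            "response": response,
                            "models": tbl.to_records(),
                        }
                    )
                    log(
                        "ou_fit",
                        response=response,
                        reconstruction=painting.reconstruction_index,
                        best=tbl.fits[tbl.best_index].spec.label(),
                    )
            _json_dump(blocks, out / "ou_fits.json")
            manifest["outputs"].append("ou_fits.json")
            report["ou_fits"] = blocks

    manifest["complete"] = True
    _json_dump(manifest, out / "MANIFEST.json")
    log("done")
    report["manifest"] = manifest
    return report
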