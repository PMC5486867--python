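"""Readers, writers, configuration, and the reproducible pipeline runner.

Two TSV/CSV input dialects are recognized by their header:

* processed — one row per selected single fixation with word properties
  (see :data:`linkedlmm.transforms.RAW_COLUMNS`); transformed and centered
  on read;
* raw sequence — one row per fixation in temporal order (``subject,
  sentence, fixation_order, word_index, char_index, duration_ms``); routed
  through the single-fixation filters, returning the qualifying fixations
  with their skipping labels.  Word properties must be merged before such
  data can be modelled.

Every pipeline run writes a manifest (JSON) capturing the configuration
snapshot, seeds, software version, convergence status and wall time, so
any output table can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    FixedTerm,
    ModelSpec,
    RandomTerm,
    preset_duration_spec,
    preset_location_spec,
)
from .linking import LINK_MODES, compare_models, fit_linked_sequential
from .simdata import (
    SimConfig,
    generate_corpus,
    slim_duration_spec,
    slim_location_spec,
)
from .transforms import (
    RAW_COLUMNS,
    RAW_SEQUENCE_COLUMNS,
    FixationTable,
    select_single_fixations,
    transform_table,
)

__all__ = [
    "read_fixation_table",
    "write_table",
    "RunManifest",
    "modelspec_from_dict",
    "simconfig_from_dict",
    "run_pipeline",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_fixation_table(path, dialect: str = "auto", n_complete: int = 83,
                        strict_location: bool = True) -> FixationTable:
    """Read a fixation report, detecting the dialect from the header.

    Processed-dialect files come back transformed and centered;
    ``strict_location=False`` admits out-of-word character indices, which
    simulator-written corpora contain.
    Raw-sequence files are filtered to qualifying single fixations (one
    trial = one subject x sentence, ordered by ``fixation_order``); the
    result carries the selection flags and skipping labels but no
    transformed covariates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = set(df.columns)
    if dialect == "auto":
        if set(RAW_COLUMNS) <= cols:
            dialect = "processed"
        elif set(RAW_SEQUENCE_COLUMNS) <= cols:
            dialect = "sequence"
        else:
            missing = [c for c in RAW_COLUMNS if c not in cols]
            raise ValueError(
                f"header matches no known dialect; processed dialect lacks "
                f"column(s) {missing}"
            )
    if dialect == "processed":
        missing = [c for c in RAW_COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        return transform_table(df, n_complete=n_complete,
                               strict_location=strict_location)
    if dialect == "sequence":
        missing = [c for c in RAW_SEQUENCE_COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        out = []
        for (subj, sent), trial in df.groupby(["subject", "sentence"],
                                              sort=True):
            trial = trial.sort_values("fixation_order")
            flags = select_single_fixations(trial["word_index"].to_numpy())
            sel = trial.reset_index(drop=True)[flags["qualifies"].to_numpy()]
            sel = sel.assign(skip=flags.loc[flags["qualifies"], "skip"].to_numpy())
            out.append(sel)
        data = (pd.concat(out, ignore_index=True) if out
                else df.iloc[0:0].assign(skip=pd.Series(dtype=int)))
        return FixationTable(data=data, centering={}, n_dropped=0)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_table(df: pd.DataFrame, path) -> None:
    """Canonical TSV output: tab-separated, '.' decimal, UTF-8."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None
    inputs: list[str]
    outputs: list[str]
    version: str = __version__
    converged: dict = dataclasses.field(default_factory=dict)
    wall_time_s: float = 0.0
    status: str = "ok"
    log: list[str] = dataclasses.field(default_factory=list)

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


_SPEC_PRESETS = {
    "psc-location": lambda: preset_location_spec(),
    "psc-duration": lambda: preset_duration_spec("none"),
    "slim-location": slim_location_spec,
    "slim-duration": slim_duration_spec,
}


def modelspec_from_dict(d: dict) -> ModelSpec:
    """Build a ModelSpec from a config mapping (or a named preset)."""
    if "preset" in d:
        name = d["preset"]
        if name not in _SPEC_PRESETS:
            raise ValueError(
                f"unknown preset {name!r}; available: {sorted(_SPEC_PRESETS)}"
            )
        return _SPEC_PRESETS[name]()
    fixed = [
        FixedTerm(t["name"], degree=int(t.get("degree", 1)), by=t.get("by"))
        for t in d["fixed"]
    ]
    random = [
        RandomTerm(r["factor"], list(r.get("covariates", ["1"])))
        for r in d.get("random", [])
    ]
    return ModelSpec(response=d["response"], fixed=fixed, random=random,
                     label=d.get("label", ""))


def simconfig_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    preset = d.pop("preset", None)
    if preset == "reduced":
        return SimConfig.reduced(**d)
    if preset in (None, "full", "psc"):
        return dataclasses.replace(SimConfig(), **d)
    raise ValueError(f"unknown simulate preset {preset!r}")


def run_pipeline(config_path, out_dir=None) -> Path:
    """Execute a configured analysis end to end.

    The YAML config names either a data file or a ``simulate`` block, the
    two model specs, the link modes to compare, and a seed.  Coefficient
    tables, the goodness-of-fit report and a manifest are written to the
    output directory.  Raises on the first failed stage after persisting a
    manifest recording the failure point.
    """
    config_path = Path(config_path)
    with open(config_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    out = Path(out_dir or cfg.get("out", "linkedlmm-out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")
    modes = cfg.get("modes", ["none", "observed", "both"])
    bad = [m for m in modes if m not in LINK_MODES]
    if bad:
        raise ValueError(f"unknown mode(s) {bad}; expected members of {LINK_MODES}")

    manifest = RunManifest(command="run", config=cfg, seed=seed,
                           inputs=[str(config_path)], outputs=[])
    t0 = time.time()
    try:
        if "simulate" in cfg:
            if seed is None:
                raise ValueError("a seed is required when simulating")
            sim = simconfig_from_dict(cfg["simulate"])
            corpus = generate_corpus(sim, int(seed))
            table = corpus.table
            sim_path = out / "corpus.tsv"
            write_table(table.data[RAW_COLUMNS], sim_path)
            write_table(corpus.truth, out / "corpus_truth.tsv")
            manifest.outputs += [str(sim_path), str(out / "corpus_truth.tsv")]
            manifest.log.append(f"simulated corpus with {len(table.data)} rows")
        elif "data" in cfg:
            table = read_fixation_table(cfg["data"])
            manifest.inputs.append(str(cfg["data"]))
            manifest.log.append(
                f"read {len(table.data)} rows ({table.n_dropped} dropped)"
            )
        else:
            raise ValueError("config must contain a 'data' path or a 'simulate' block")

        spec1 = modelspec_from_dict(cfg.get("location_spec",
                                            {"preset": "slim-location"}))
        spec2 = modelspec_from_dict(cfg.get("duration_spec",
                                            {"preset": "slim-duration"}))

        report = compare_models(table, spec1, spec2, modes=modes)
        write_table(report.rows, out / "fit_report.tsv")
        manifest.outputs.append(str(out / "fit_report.tsv"))

        for mode in modes:
            lf = fit_linked_sequential(table, spec1, spec2, mode=mode)
            write_table(lf.fit2.coef_table(), out / f"coefficients_{mode}.tsv")
            manifest.outputs.append(str(out / f"coefficients_{mode}.tsv"))
            manifest.converged[mode] = bool(lf.fit2.converged)
            if lf.link_columns:
                write_table(lf.link_table(), out / f"link_{mode}.tsv")
                manifest.outputs.append(str(out / f"link_{mode}.tsv"))
        manifest.log.append(
            "centering constants: "
            + json.dumps(getattr(table, "centering", {}))
        )
    except Exception as exc:
        manifest.status = f"failed: {exc}"
        manifest.wall_time_s = time.time() - t0
        manifest.write(out / "manifest.json")
        raise
    manifest.wall_time_s = time.time() - t0
    manifest.write(out / "manifest.json")
    return out
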