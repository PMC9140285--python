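"""File formats, run configuration and the end-to-end pipeline.

All formats are plain text and round-trip losslessly: ternary state matrices
as TSV with a header of neuron identifiers, models as JSON (fields, upper
triangle of couplings, gauge tag), synchrony distributions as TSV, Fisher
matrices as dense TSV with a JSON sidecar recording direction ordering and
metadata, spectrum fits as JSON.  Floats are written with 17 significant
digits so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fim import FisherMatrix
from .model import PottsModel, StateMatrix
from .spectrum import SpectrumFit
from .synchrony import SynchronyDistribution


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


# ---------------------------------------------------------------------------
# StateMatrix <-> TSV
# ---------------------------------------------------------------------------

def write_state_matrix(states: StateMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(states.neuron_ids) + "\n")
        for row in states.values:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_state_matrix(path: str | Path) -> StateMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} cells")
            try:
                row = [int(c) for c in cells]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer cell") from exc
            for col, v in enumerate(row):
                if v not in (-1, 0, 1):
                    raise ValueError(
                        f"{path}:{lineno}: column {col} ({header[col]}): "
                        f"state value {v} not in {{-1, 0, 1}}"
                    )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return StateMatrix(values=np.array(rows, dtype=np.int8), neuron_ids=header)


def read_traces(path: str | Path) -> np.ndarray:
    """Continuous time x neurons traces from TSV/CSV (header optional)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    return df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# PottsModel <-> JSON
# ---------------------------------------------------------------------------

def write_model(model: PottsModel, path: str | Path) -> None:
    N = model.N
    payload = {
        "N": N,
        "gauge": model.gauge,
        "h": [[_fmt(v) for v in row] for row in model.h],
        "J_upper": [
            [m, t, _fmt(model.J[m, t])]
            for m in range(N)
            for t in range(m + 1, N)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_model(path: str | Path) -> PottsModel:
    payload = json.loads(Path(path).read_text())
    for key in ("N", "gauge", "h", "J_upper"):
        if key not in payload:
            raise ValueError(f"{path}: model JSON missing required key {key!r}")
    N = int(payload["N"])
    h = np.array([[float(v) for v in row] for row in payload["h"]])
    if h.shape != (N, 3):
        raise ValueError(f"{path}: h must be {N} x 3")
    J = np.zeros((N, N))
    for m, t, v in payload["J_upper"]:
        J[int(m), int(t)] = J[int(t), int(m)] = float(v)
    return PottsModel(h=h, J=J, gauge=payload["gauge"])


# ---------------------------------------------------------------------------
# SynchronyDistribution <-> TSV
# ---------------------------------------------------------------------------

def write_synchrony(dist: SynchronyDistribution, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        if dist.granularity == "fine":
            fh.write("n1\tn2\tn3\tprob\n")
            for (n1, n2, n3), p in zip(dist.support, dist.probs):
                fh.write(f"{n1}\t{n2}\t{n3}\t{_fmt(p)}\n")
        else:
            fh.write("n1\tprob\n")
            for n1, p in zip(dist.support, dist.probs):
                fh.write(f"{n1}\t{_fmt(p)}\n")


def read_synchrony(path: str | Path) -> SynchronyDistribution:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) == ["n1", "n2", "n3", "prob"]:
        support = [tuple(int(v) for v in row) for row in df[["n1", "n2", "n3"]].to_numpy()]
        return SynchronyDistribution("fine", support, df["prob"].to_numpy())
    if list(df.columns) == ["n1", "prob"]:
        return SynchronyDistribution(
            "coarse", [int(v) for v in df["n1"]], df["prob"].to_numpy()
        )
    raise ValueError(f"{path}: unrecognized synchrony columns {list(df.columns)}")


# ---------------------------------------------------------------------------
# FisherMatrix <-> TSV + JSON sidecar
# ---------------------------------------------------------------------------

def write_fisher(F: FisherMatrix, path: str | Path) -> None:
    """Dense TSV of the matrix; sidecar <path>.json holds directions/metadata."""
    path = Path(path)
    with path.open("w") as fh:
        for row in F.values:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    sidecar = {
        "directions": [list(d) for d in F.directions],
        "granularity": F.granularity,
        "estimator": F.estimator,
        "kind": F.kind,
        "mc_meta": F.mc_meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1) + "\n"
    )


def read_fisher(path: str | Path) -> FisherMatrix:
    path = Path(path)
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FisherMatrix(
        values=values,
        directions=[tuple(d) for d in sidecar["directions"]],
        granularity=sidecar["granularity"],
        estimator=sidecar["estimator"],
        kind=sidecar["kind"],
        mc_meta=sidecar.get("mc_meta", {}),
    )


# ---------------------------------------------------------------------------
# SpectrumFit <-> JSON
# ---------------------------------------------------------------------------

def write_spectrum_fit(fit: SpectrumFit, path: str | Path) -> None:
    payload = {k: v for k, v in dataclasses.asdict(fit).items()}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_spectrum_fit(path: str | Path) -> SpectrumFit:
    return SpectrumFit(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "N": 6,
    "seed": 0,
    "field_scale": 0.5,
    "coupling_scale": 0.3,
    "coupling_sign_fraction": 0.5,
    "T": 2000,
    "granularity": "fine",
    "fit_tolerance": 1e-6,
    "eps_display": 1e-4,
    "M_shuffles": 10,
    "out_dir": "synchfim_run",
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    raw = path.read_text()
    cfg = yaml.safe_load(raw) if path.suffix in (".yml", ".yaml") else json.loads(raw)
    merged = dict(DEFAULT_CONFIG)
    merged.update(cfg or {})
    return merged


def run_pipeline(config: dict) -> dict:
    """Synthetic end-to-end run: simulate -> fit -> synchrony -> FIM -> modes
    -> spectrum -> null comparisons.  Writes every artifact plus a provenance
    log and returns the artifact paths keyed by stage.
    """
    from . import __version__
    from .fim import (
        canonical_fim,
        eigenmodes,
        observable_fim,
        pivotal_neurons,
        shuffled_coupling_null,
        uniformity,
    )
    from .fit import fit_independent, fit_pairwise_exact
    from .model import observables_from_states
    from .spectrum import fit_truncated_power_law, truncation_rank
    from .synchrony import synchrony_distribution
    from .synthetic import GroundTruthSpec, generate_ground_truth_model, sample_states

    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    spec = GroundTruthSpec(
        N=cfg["N"],
        field_scale=cfg["field_scale"],
        coupling_scale=cfg["coupling_scale"],
        coupling_sign_fraction=cfg["coupling_sign_fraction"],
        seed=cfg["seed"],
    )
    if cfg.get("states_path"):
        src = Path(cfg["states_path"])
        if not src.exists():
            raise FileNotFoundError(f"pipeline stage 'input': missing input path {src}")
        states = stage("input")(lambda: read_state_matrix(src))
    else:
        truth = stage("simulate")(lambda: generate_ground_truth_model(spec))
        states = stage("simulate")(
            lambda: sample_states(truth, cfg["T"], seed=cfg["seed"] + 1)
        )
        write_model(truth, out / "ground_truth.json")
    write_state_matrix(states, out / "states.tsv")
    artifacts["states"] = str(out / "states.tsv")

    obs = observables_from_states(states)
    model, report = stage("fit")(
        lambda: fit_pairwise_exact(obs, tolerance=cfg["fit_tolerance"], T=states.T)
    )
    write_model(model, out / "model.json")
    artifacts["model"] = str(out / "model.json")

    sync = stage("synchrony")(
        lambda: synchrony_distribution(model, granularity=cfg["granularity"])
    )
    write_synchrony(sync, out / "synchrony.tsv")
    artifacts["synchrony"] = str(out / "synchrony.tsv")

    F = stage("fim")(lambda: observable_fim(model, granularity=cfg["granularity"]))
    write_fisher(F, out / "fim.tsv")
    artifacts["fim"] = str(out / "fim.tsv")

    modes = stage("eigen")(lambda: eigenmodes(F))
    lam = np.array([mode.eigenvalue for mode in modes])
    col_u = np.stack([uniformity(mode)[1] for mode in modes])
    pivotal = pivotal_neurons(modes, percentile=99.0)
    (out / "modes.json").write_text(
        json.dumps(
            {
                "eigenvalues": [_fmt(v) for v in lam],
                "column_uniformity_max": [_fmt(v) for v in col_u.max(axis=0)],
                "pivotal_flags": [float(v) for v in pivotal],
            },
            indent=1,
        )
        + "\n"
    )
    artifacts["modes"] = str(out / "modes.json")

    z_cut = truncation_rank(lam, n_neurons=model.N)
    sfit = stage("spectrum")(
        lambda: fit_truncated_power_law(lam, Z_cut=max(3, z_cut))
    )
    write_spectrum_fit(sfit, out / "spectrum.json")
    artifacts["spectrum"] = str(out / "spectrum.json")

    def null_spectra():
        indep = fit_independent(obs, T=states.T)
        shuffled = shuffled_coupling_null(model, seed=cfg["seed"] + 2)
        return {
            "independent": observable_fim(indep, granularity=cfg["granularity"]).eigenvalues(),
            "shuffled": observable_fim(shuffled, granularity=cfg["granularity"]).eigenvalues(),
            "canonical": canonical_fim(model, granularity=cfg["granularity"]).eigenvalues(),
        }

    nulls = stage("nulls")(null_spectra)
    (out / "nulls.json").write_text(
        json.dumps(
            {k: [_fmt(x) for x in v] for k, v in nulls.items()}, indent=1
        )
        + "\n"
    )
    artifacts["nulls"] = str(out / "nulls.json")

    provenance = {
        "package": "synchfim",
        "version": __version__,
        "numpy": np.__version__,
        "config": {k: cfg[k] for k in sorted(cfg)},
        "fit_report": dataclasses.asdict(report),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1) + "\n")
    artifacts["provenance"] = str(out / "provenance.json")
    return artifacts
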