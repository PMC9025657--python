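"""Configured, logged, reproducible end-to-end runs.

A run consumes a plain ``key: value`` config (YAML subset), executes the
analysis stages — threshold summaries, per-subject network extraction,
group consensus, per-subject PI extremes, semiology consensus — over either
the packaged clinical tables or a simulated cohort, and leaves behind a run
directory whose manifest records the config hash and a checksum of every
output, so identical configs and seeds yield byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, network, phantom, semiology
from . import atlas as _atlas

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG = {
    # input tables; "packaged" selects the shipped fixtures
    "pi_interictal": "packaged",
    "pi_ictal": "packaged",
    "thresholds": "packaged",       # published per-subject cut-offs
    "subjects": "packaged",
    "sequences": "packaged",
    # analysis parameters
    "threshold_method": "tree",     # used when thresholds are recomputed
    "traditional_k": 1.0,
    "min_subjects": None,           # default ceil(n_group / 2)
    "decimals": 3,
    # optional simulation stage
    "simulate": False,
    "n_per_group": 5,
    "delta_inter": 0.15,
    "delta_ictal": 0.25,
    "sigma": 0.07,
    "seed": 0,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise StageError("config", f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _load(cfg, key, loader, packaged):
    value = cfg[key]
    return packaged() if value == "packaged" else loader(value)


def _write_table(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str,
                 decimals: int | None = None) -> None:
    out = df.copy()
    if decimals is not None:
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].round(decimals)
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={cfg_hash}\n")
        out.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute all configured stages; returns the run directory.

    Outputs: ``threshold_summary.tsv``, ``networks.tsv``, ``consensus.tsv``,
    ``extremes_per_subject.tsv``, ``extremes_summary.tsv``,
    ``semiology_consensus.tsv``, flowchart ``.dot`` files, optional
    simulation outputs, plus ``manifest.json`` and ``log.txt``.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    cfg_hash = _config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config hash {cfg_hash}"]
    dec = cfg["decimals"]

    def stage(name):
        log.append(f"stage {name}")

    try:
        stage("load")
        subjects = _load(cfg, "subjects", _atlas.read_subject_table,
                         datasets.load_subjects)
        pi = pd.concat(
            [
                _load(cfg, "pi_interictal", _atlas.read_perfusion_table,
                      lambda: datasets.load_perfusion("interictal")),
                _load(cfg, "pi_ictal", _atlas.read_perfusion_table,
                      lambda: datasets.load_perfusion("ictal")),
            ],
            ignore_index=True,
        )
        log.append(f"  subjects={len(subjects)} pi_rows={len(pi)}")
    except Exception as e:  # noqa: BLE001 - re-tagged with stage name
        raise StageError("load", str(e)) from e

    try:
        stage("threshold")
        if cfg["thresholds"] == "packaged":
            thresholds = datasets.load_thresholds()
        elif cfg["thresholds"] in ("recompute", None):
            thresholds = network.subject_thresholds(
                pi, method=cfg["threshold_method"], k=cfg["traditional_k"]
            )[["subject_id", "state", "threshold"]]
        else:
            thresholds = pd.read_csv(cfg["thresholds"], sep="\t", comment="#",
                                     dtype={"subject_id": str})
        summaries = []
        for state, g in thresholds.groupby("state"):
            s = network.summarize_thresholds(g["threshold"])
            summaries.append({"state": state, **s.__dict__})
        _write_table(pd.DataFrame(summaries), out / "threshold_summary.tsv",
                     "threshold", cfg_hash, dec)
        log.append(f"  thresholds={len(thresholds)}")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("threshold", str(e)) from e

    try:
        stage("network")
        thr_map = {
            (r["subject_id"], r["state"]): float(r["threshold"])
            for _, r in thresholds.iterrows()
        }
        net_rows = []
        nets_by_group: dict = {}
        groups = subjects.set_index("subject_id")["epilepsy_group"]
        for (sid, state), t in thr_map.items():
            sub = pi[(pi["subject_id"] == sid) & (pi["state"] == state)]
            members = network.extract_network(sub, t, state)
            for name, side in sorted(members):
                pi_val = float(
                    sub[(sub["name"] == name) & (sub["side"] == side)]["pi"].iloc[0]
                )
                net_rows.append({"subject_id": sid, "state": state,
                                 "name": name, "side": side, "pi": pi_val,
                                 "threshold": t})
            g = groups.get(sid)
            nets_by_group.setdefault((g, state), []).append((state, members))
        _write_table(
            pd.DataFrame(net_rows, columns=["subject_id", "state", "name",
                                            "side", "pi", "threshold"]),
            out / "networks.tsv", "network", cfg_hash, dec)

        cons_rows = []
        for (g, state), nets in sorted(nets_by_group.items()):
            n_min = cfg["min_subjects"] or int(np.ceil(len(nets) / 2))
            cons = network.consensus_network(nets, n_min)
            for _, r in cons.iterrows():
                cons_rows.append({"epilepsy_group": g, "state": state,
                                  "min_subjects": n_min, **r.to_dict()})
        _write_table(
            pd.DataFrame(cons_rows, columns=["epilepsy_group", "state",
                                             "min_subjects", "name", "side",
                                             "n_subjects"]),
            out / "consensus.tsv", "network", cfg_hash, dec)
        log.append(f"  network_rows={len(net_rows)} consensus_rows={len(cons_rows)}")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("network", str(e)) from e

    try:
        stage("summarize")
        per_frames, sum_frames = [], []
        for state in ("interictal", "ictal"):
            if not (pi["state"] == state).any():
                continue
            per, summ = network.per_patient_extremes(pi, state)
            per.insert(0, "state", state)
            summ.insert(0, "state", state)
            per_frames.append(per)
            sum_frames.append(summ)
        _write_table(pd.concat(per_frames, ignore_index=True),
                     out / "extremes_per_subject.tsv", "summarize", cfg_hash, dec)
        _write_table(pd.concat(sum_frames, ignore_index=True),
                     out / "extremes_summary.tsv", "summarize", cfg_hash, dec)
    except Exception as e:  # noqa: BLE001
        raise StageError("summarize", str(e)) from e

    try:
        stage("semiology")
        seq_path = (datasets.load_sequences_path()
                    if cfg["sequences"] == "packaged" else cfg["sequences"])
        seqs = semiology.parse_sequences(seq_path)
        group_of = dict(zip(subjects["subject_id"], subjects["epilepsy_group"]))
        sem_rows = []
        for g in sorted(set(group_of.values())):
            gs = semiology.group_consensus(seqs, group_of, g)
            (out / f"flowchart_{g}.dot").write_text(
                semiology.render_flowchart(gs) + "\n")
            for code, med, (lo, hi), n in gs.motifs:
                sem_rows.append({"epilepsy_group": g, "code": code,
                                 "median_onset_s": med, "onset_min_s": lo,
                                 "onset_max_s": hi, "n_subjects": n})
        _write_table(pd.DataFrame(sem_rows), out / "semiology_consensus.tsv",
                     "semiology", cfg_hash, dec)
        log.append(f"  sequences={len(seqs)}")
    except Exception as e:  # noqa: BLE001
        raise StageError("semiology", str(e)) from e

    if cfg["simulate"]:
        try:
            stage("simulate")
            n = int(cfg["n_per_group"])
            cohort = phantom.simulate_cohort(
                {"TLE": n, "FLE": n, "PQE": n},
                delta_inter=cfg["delta_inter"], delta_ictal=cfg["delta_ictal"],
                sigma=cfg["sigma"], seed=int(cfg["seed"]),
            )
            _write_table(cohort.roster, out / "sim_roster.tsv", "simulate",
                         cfg_hash, dec)
            _write_table(cohort.perfusion, out / "sim_perfusion.tsv",
                         "simulate", cfg_hash, dec)
            _write_table(cohort.truth, out / "sim_truth.tsv", "simulate",
                         cfg_hash, dec)
            scores = network.recovery_scores(
                cohort.perfusion, cohort.roster, cohort.truth,
                method="traditional", k=cfg["traditional_k"],
                min_subjects=cfg["min_subjects"],
            )
            _write_table(pd.DataFrame([scores]), out / "sim_recovery.tsv",
                         "simulate", cfg_hash, dec)
            log.append(f"  sim_subjects={len(cohort.roster)}")
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", str(e)) from e

    stage("manifest")
    checksums = {}
    for p in sorted(out.iterdir()):
        if p.name in ("manifest.json", "log.txt") or p.is_dir():
            continue
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"config": {k: cfg[k] for k in sorted(cfg)},
                "config_hash": cfg_hash, "outputs": checksums}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out
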