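"""End-to-end orchestration: simulate -> states -> cycles -> associate.

A single run configuration (YAML-serialisable) plus a global seed fully
determine every output; per-stage seeds are derived from the global seed so
stages can be re-run independently. Each run writes a manifest recording the
derived seeds, output hashes and row counts, and re-running with the same
configuration reproduces the tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .network_states import (
    assign_states,
    extract_features,
    nmf_fit,
    records_from_labels,
    stability_select_rank,
)
from .spike_cycles import CycleConfig, SeizurePhases, assign_seizure_phases, extract_cycles
from .synthetic_data import SynthConfig, simulate_cohort
from .temporal_stats import (
    AssociationResult,
    circ_linear_rank_corr,
    duration_phase_test,
    duration_vs_time,
    fdr_correct,
    occurrence_vs_time,
    plv,
    plv_occurrence_test,
)

__all__ = ["RunConfig", "run_pipeline", "associate_cohort", "results_to_frame"]


def _stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    patient: str = "synthetic-01"
    stages: tuple[str, ...] = ("simulate", "states", "cycles", "associate")
    synth: dict = field(default_factory=dict)
    rank_range: tuple[int, int] = (2, 8)
    n_repeats: int = 20
    stability_tau: float = 0.01
    rank: int | None = None            # fixed rank skips stability selection
    cycle: dict = field(default_factory=dict)
    n_perm: int = 10_000
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "rank_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def associate_cohort(
    occurrence: pd.DataFrame,
    duration: pd.DataFrame,
    onset_days: dict,
    phases: SeizurePhases,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    patient: str = "patient",
) -> list[AssociationResult]:
    """All four association analyses for one patient, FDR-corrected cohort-wide.

    Tests whose preconditions fail (too few seizures, constant durations,
    always-present states for occurrence) are recorded with ``excluded=True``
    and kept out of the FDR family.
    """
    rng_root = np.random.SeedSequence(seed)
    results: list[AssociationResult] = []
    sid_index = {sid: i for i, sid in enumerate(phases.seizure_ids)}
    always = set(occurrence.attrs.get("excluded_from_occurrence", []))

    def _next_rng() -> np.random.Generator:
        return np.random.default_rng(rng_root.spawn(1)[0])

    for sns in occurrence.columns:
        with_mask = occurrence[sns].to_numpy()
        ids = occurrence.index.to_numpy()
        times = np.array([onset_days[i] for i in ids])

        # occurrence vs time since implantation
        if int(sns) not in always and with_mask.any() and (~with_mask).any():
            auc, p = occurrence_vs_time(times[with_mask], times[~with_mask])
            results.append(
                AssociationResult(patient, int(sns), "occurrence", "time_since_implantation",
                                  "AUC", auc, auc - 0.5, p, "rank-sum")
            )

        # duration vs time
        sub = duration[duration["sns"] == sns]
        try:
            rho, p = duration_vs_time(sub["windows"], sub["onset_day"])
            results.append(
                AssociationResult(patient, int(sns), "duration", "time_since_implantation",
                                  "spearman_rho", rho, rho, p, "spearman-t")
            )
        except ValueError:
            results.append(
                AssociationResult(patient, int(sns), "duration", "time_since_implantation",
                                  "spearman_rho", np.nan, None, np.nan, "spearman-t",
                                  excluded=True)
            )

        # occurrence flags in the order of phases.seizure_ids
        in_state = np.array([bool(occurrence.loc[sid, sns]) for sid in phases.seizure_ids])

        for c, cycle_id in enumerate(phases.cycle_ids):
            valid = phases.valid[:, c]
            phi_all = phases.phases[valid, c]
            phi_with = phases.phases[valid & in_state, c]

            # occurrence vs cycle phase (PLV permutation test)
            if int(sns) not in always:
                try:
                    r_obs, d_r, p = plv_occurrence_test(
                        phi_with, phi_all, n_perm=n_perm, seed=_next_rng()
                    )
                    results.append(
                        AssociationResult(patient, int(sns), "occurrence", cycle_id,
                                          "PLV", r_obs, d_r, p, "permutation", n_perm,
                                          extra={"psi": plv(phi_with).psi})
                    )
                except ValueError:
                    results.append(
                        AssociationResult(patient, int(sns), "occurrence", cycle_id,
                                          "PLV", np.nan, None, np.nan, "permutation",
                                          n_perm, excluded=True)
                    )

            # duration vs cycle phase (D shuffle test)
            svalid = {sid: phases.valid[sid_index[sid], c] for sid in phases.seizure_ids}
            sub_c = sub[[svalid.get(sid, False) for sid in sub["seizure_id"]]]
            phi_d = np.array([phases.phases[sid_index[sid], c] for sid in sub_c["seizure_id"]])
            try:
                D_obs, p = duration_phase_test(
                    sub_c["windows"].to_numpy(), phi_d, n_perm=n_perm, seed=_next_rng()
                )
                results.append(
                    AssociationResult(patient, int(sns), "duration", cycle_id,
                                      "D", D_obs, D_obs, p, "permutation", n_perm)
                )
            except ValueError:
                results.append(
                    AssociationResult(patient, int(sns), "duration", cycle_id,
                                      "D", np.nan, None, np.nan, "permutation", n_perm,
                                      excluded=True)
                )

    return fdr_correct(results, alpha=alpha)


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "patient": r.patient,
                "sns": r.sns,
                "feature": r.feature,
                "factor": r.factor,
                "statistic": r.statistic,
                "value": r.value,
                "effect": r.effect,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.fdr_significant,
                "excluded": r.excluded,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}
    cohort_path = out / "cohort.h5"

    if "simulate" in cfg.stages:
        scfg = SynthConfig(**{**cfg.synth, "seed": _stage_seed(cfg.seed, "simulate")})
        cohort = simulate_cohort(scfg)
        _io.write_cohort(cohort_path, cohort)
        _io.write_annotations_csv(out / "annotations.csv", cohort)
        _io.write_spike_rate_csv(out / "spike_rate.csv", cohort.time_days, cohort.spike_rate)
        manifest["stages"]["simulate"] = {
            "seed": scfg.seed,
            "n_seizures": len(cohort.seizures),
            "n_windows": int(sum(s.n_windows for s in cohort.seizures)),
        }

    if "states" in cfg.stages:
        if not cohort_path.exists():
            raise FileNotFoundError("states stage requires cohort.h5 (run simulate first)")
        feats, onsets, ids = _io.read_features(cohort_path)
        X = np.concatenate([f.T for f in feats], axis=1)
        wmap = np.concatenate([np.full(f.shape[0], i) for i, f in enumerate(feats)])
        seed = _stage_seed(cfg.seed, "states")
        if cfg.rank is not None:
            k, curve = cfg.rank, {}
        else:
            lo, hi = cfg.rank_range
            k, curve = stability_select_rank(
                X, range(lo, hi + 1), n_repeats=cfg.n_repeats, seed=seed, tau=cfg.stability_tau
            )
        model = nmf_fit(X, k, seed=seed)
        labels = assign_states(model)
        records = records_from_labels(labels, wmap, onsets, ids)
        occ, dur = extract_features(records, k)
        occ.to_csv(out / "occurrence.tsv", sep="\t")
        dur.to_csv(out / "duration.tsv", sep="\t", index=False)
        pd.DataFrame({"window": np.arange(labels.size), "seizure": wmap, "sns": labels}).to_csv(
            out / "labels.tsv", sep="\t", index=False
        )
        np.savetxt(out / "W.tsv", model.W, delimiter="\t")
        manifest["stages"]["states"] = {
            "seed": seed,
            "rank": int(k),
            "stability_curve": {int(r): float(v) for r, v in curve.items()},
        }

    if "cycles" in cfg.stages:
        t_days, rate = _io.read_spike_rate(cohort_path)
        ccfg = CycleConfig(**{"emd_seed": _stage_seed(cfg.seed, "cycles"), **cfg.cycle})
        cycles, gap_mask = extract_cycles(rate, ccfg)
        ann = pd.read_csv(out / "annotations.csv")
        sp = assign_seizure_phases(
            cycles, ann["onset_day"].to_numpy(), ann["seizure_id"].tolist(), gap_mask, ccfg
        )
        pd.DataFrame(
            {
                "cycle_id": [c.cycle_id for c in cycles],
                "timescale": [c.timescale for c in cycles],
                "avg_period_days": [c.avg_period for c in cycles],
                "power_fraction": [c.power_fraction for c in cycles],
            }
        ).to_csv(out / "cycles.tsv", sep="\t", index=False)
        ph = pd.DataFrame(sp.phases, columns=sp.cycle_ids)
        ph.insert(0, "seizure_id", sp.seizure_ids)
        for i, cid in enumerate(sp.cycle_ids):
            ph[f"{cid}_valid"] = sp.valid[:, i]
        ph.to_csv(out / "seizure_phases.tsv", sep="\t", index=False)
        manifest["stages"]["cycles"] = {
            "seed": ccfg.emd_seed,
            "n_cycles": len(cycles),
            "periods_days": [float(c.avg_period) for c in cycles],
        }

    if "associate" in cfg.stages:
        occ = pd.read_csv(out / "occurrence.tsv", sep="\t", index_col="seizure_id")
        occ.columns = occ.columns.astype(int)
        occ = occ.astype(bool)
        dur = pd.read_csv(out / "duration.tsv", sep="\t")
        ann = pd.read_csv(out / "annotations.csv")
        ph = pd.read_csv(out / "seizure_phases.tsv", sep="\t")
        cycle_ids = [c for c in ph.columns if c not in ("seizure_id",) and not c.endswith("_valid")]
        sp = SeizurePhases(
            seizure_ids=ph["seizure_id"].tolist(),
            cycle_ids=cycle_ids,
            phases=ph[cycle_ids].to_numpy(),
            valid=ph[[f"{c}_valid" for c in cycle_ids]].to_numpy(dtype=bool),
        )
        always = occ.columns[occ.all(axis=0)].astype(int).tolist()
        occ.attrs["excluded_from_occurrence"] = always
        onset_days = dict(zip(ann["seizure_id"], ann["onset_day"]))
        results = associate_cohort(
            occ, dur, onset_days, sp,
            n_perm=cfg.n_perm, seed=_stage_seed(cfg.seed, "associate"),
            alpha=cfg.alpha, patient=cfg.patient,
        )
        frame = results_to_frame(results)
        frame.to_csv(out / "results.tsv", sep="\t", index=False)
        tested = frame[~frame["excluded"]]
        summary = {
            "patient": cfg.patient,
            "n_tests": int(len(tested)),
            "n_significant": int(tested["significant"].sum()),
            "by_feature_factor": {
                f"{f}|{g}": int(grp["significant"].sum())
                for (f, g), grp in tested.groupby(["feature", "factor"])
            },
        }
        _io.write_json(out / "summary.json", summary)
        manifest["stages"]["associate"] = {
            "seed": _stage_seed(cfg.seed, "associate"),
            "n_tests": summary["n_tests"],
            "n_significant": summary["n_significant"],
        }

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = {"sha256": _sha256(p), "bytes": p.stat().st_size}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
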