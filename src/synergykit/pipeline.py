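"""End-to-end orchestration of the analysis chain.

One call takes a set of session files, a myotomal chart and a config, and
produces the complexity table, spinal maps, synergy sets, cross-session
matching and the statistical report, serialized as TSV/JSON with a manifest.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import StageError, SynergyKitError
from .hfd import HFDParams, complexity_table
from .matching import MatchResult, match_cohort
from .preprocess import PreprocessedSession, preprocess_session
from .session import SessionRecord, read_session
from .spinalmap import MyotomalChart, SpinalMap, load_chart, map_to_segments
from .stats import StatsReport, run_group_analysis
from .synergy import SynergySet, extract_synergies

SetKey = tuple[str, int, str, str]   # (participant, session, movement, condition)


@dataclass
class ReportBundle:
    """Everything one run produces."""

    hfd_table: pd.DataFrame
    spinal_maps: dict[SetKey, SpinalMap]
    synergy_sets: dict[SetKey, SynergySet]
    match_results: dict[tuple[str, str], MatchResult]
    stats_report: StatsReport
    preprocessed: dict[tuple[str, int], PreprocessedSession] = field(repr=False,
                                                                     default_factory=dict)


def _session_id(record: SessionRecord) -> str:
    return f"{record.participant_id}/s{record.session_index}"


def run_full_analysis(
    sessions: list[str | Path | SessionRecord],
    chart: str | Path | MyotomalChart | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    r2_equivalence_k: int = 4,
    lazy_curve: bool = False,
) -> ReportBundle:
    """Run preprocessing, complexity, spinal mapping, synergy extraction,
    cross-session matching and group statistics over a list of sessions.

    Deterministic given ``config.seed``.  Any stage failure raises
    :class:`StageError` naming the stage and the offending session.  With
    ``out_dir`` every product is serialized plus a machine-readable manifest.
    """
    config = config or PipelineConfig()
    if not sessions:
        raise SynergyKitError("need at least one session")
    if not isinstance(chart, MyotomalChart):
        chart = load_chart(chart)

    records: list[SessionRecord] = []
    for s in sessions:
        if isinstance(s, SessionRecord):
            records.append(s)
        else:
            try:
                records.append(read_session(s, config.layout))
            except Exception as exc:
                raise StageError("read_session", str(s), exc) from exc

    hfd_frames = []
    spinal_maps: dict[SetKey, SpinalMap] = {}
    synergy_sets: dict[SetKey, SynergySet] = {}
    preprocessed: dict[tuple[str, int], PreprocessedSession] = {}
    hfd_params = HFDParams(k_max=config.hfd_kmax)
    ens_counter = 0
    for rec in records:
        sid = _session_id(rec)
        try:
            prep = preprocess_session(rec, config)
        except Exception as exc:
            raise StageError("preprocess", sid, exc) from exc
        preprocessed[(rec.participant_id, rec.session_index)] = prep
        try:
            hfd_frames.append(complexity_table(
                prep.trials_raw, rec.channel_names, hfd_params,
                participant_id=rec.participant_id,
                session_index=rec.session_index))
        except Exception as exc:
            raise StageError("complexity", sid, exc) from exc
        for env in prep.ensembles:
            key: SetKey = (rec.participant_id, rec.session_index,
                           env.movement_id, env.condition)
            try:
                spinal_maps[key] = map_to_segments(env, chart)
            except Exception as exc:
                raise StageError("spinal_map", sid, exc) from exc
            try:
                sub_seed = int(np.random.SeedSequence(
                    (config.seed, ens_counter)).generate_state(1)[0] % (2**31))
                synergy_sets[key] = extract_synergies(
                    env, config, seed=sub_seed, lazy_curve=lazy_curve)
            except Exception as exc:
                raise StageError("synergy_extraction", sid, exc) from exc
            ens_counter += 1
    hfd_table = pd.concat(hfd_frames, ignore_index=True)

    # cross-session matching per (movement, condition); the curve's stored
    # fits let every set be re-read at a common rank without refitting
    match_results: dict[tuple[str, str], MatchResult] = {}
    by_cell: dict[tuple[str, str], list[SetKey]] = {}
    for key in synergy_sets:
        by_cell.setdefault((key[2], key[3]), []).append(key)
    for cell, keys in sorted(by_cell.items()):
        if len(keys) < 2:
            continue
        sets = [synergy_sets[k] for k in sorted(keys)]
        k_common = Counter(s.k for s in sets).most_common()
        k_common = min(k for k, c in k_common if c == k_common[0][1])
        aligned = []
        for s in sets:
            if s.k == k_common or k_common not in s.fits:
                aligned.append(s)
            else:
                fit = s.fits[k_common]
                aligned.append(SynergySet(
                    W=fit.W, A=fit.A, k=k_common, r2_curve=s.r2_curve,
                    ks=s.ks, residual=fit.residual, threshold_met=s.threshold_met,
                    movement_id=s.movement_id, condition=s.condition))
        if len({s.k for s in aligned}) == 1:
            match_results[cell] = match_cohort(aligned)

    # R^2 at the equivalence rank, per group, averaged over each session's cells
    r2_values: dict[str, list[float]] = {}
    group_of = {(r.participant_id, r.session_index): r.group for r in records}
    per_session: dict[tuple[str, int], list[float]] = {}
    for key, s in synergy_sets.items():
        idx = np.flatnonzero(s.ks == r2_equivalence_k)
        if idx.size and np.isfinite(s.r2_curve[idx[0]]):
            per_session.setdefault((key[0], key[1]), []).append(
                float(s.r2_curve[idx[0]]))
    for sk, vals in per_session.items():
        r2_values.setdefault(group_of[sk], []).append(float(np.mean(vals)))
    r2_arrays = {g: np.asarray(v) for g, v in r2_values.items()
                 if len(v) >= 3}

    try:
        stats_report = run_group_analysis(hfd_table, r2_values=r2_arrays or None)
    except Exception as exc:
        raise StageError("group_statistics", "cohort", exc) from exc

    bundle = ReportBundle(
        hfd_table=hfd_table, spinal_maps=spinal_maps,
        synergy_sets=synergy_sets, match_results=match_results,
        stats_report=stats_report, preprocessed=preprocessed,
    )
    if out_dir is not None:
        serialize_bundle(bundle, out_dir, config)
    return bundle


def serialize_bundle(bundle: ReportBundle, out_dir: str | Path,
                     config: PipelineConfig) -> None:
    """Write every product as TSV/JSON plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def _write_tsv(df: pd.DataFrame, rel: str, index: bool = False) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        files.append(rel)

    _write_tsv(bundle.hfd_table, "hfd.tsv")
    _write_tsv(bundle.stats_report.comparisons, "stats.tsv")
    for key, sm in bundle.spinal_maps.items():
        rel = "spinalmap/{}_s{}_{}_{}.tsv".format(*key)
        _write_tsv(pd.DataFrame(sm.activity, index=list(sm.segments)), rel,
                   index=True)
    for key, s in bundle.synergy_sets.items():
        base = "synergy/{}_s{}_{}_{}".format(*key)
        _write_tsv(pd.DataFrame(s.W), base + "_W.tsv")
        _write_tsv(pd.DataFrame(s.A), base + "_A.tsv")
        _write_tsv(pd.DataFrame({"k": s.ks, "r2": s.r2_curve}), base + "_r2.tsv")
        meta = {"k": s.k, "threshold_met": s.threshold_met,
                "residual": s.residual, "movement": s.movement_id,
                "condition": s.condition}
        (out / (base + "_meta.json")).write_text(json.dumps(meta, indent=1))
        files.append(base + "_meta.json")
    match_json = {
        f"{mov}|{cond}": {
            "template_index": mr.template_index,
            "permutations": [p.tolist() for p in mr.permutations],
            "similarities": [s.tolist() for s in mr.similarities],
            "activation_correlations": [a.tolist()
                                        for a in mr.activation_correlations],
        }
        for (mov, cond), mr in bundle.match_results.items()
    }
    (out / "match.json").write_text(json.dumps(match_json, indent=1))
    files.append("match.json")
    summary = {
        "bonferroni": {
            "alpha": bundle.stats_report.threshold.alpha,
            "m": bundle.stats_report.threshold.m,
            "exact": bundle.stats_report.threshold.exact,
            "display": bundle.stats_report.threshold.display,
        },
        "skipped_comparisons": bundle.stats_report.skipped,
        "equivalence": None if bundle.stats_report.equivalence is None else {
            "equivalent": bundle.stats_report.equivalence.equivalent,
            "p": bundle.stats_report.equivalence.p,
            "margin": bundle.stats_report.equivalence.margin,
        },
        "seed": config.seed,
    }
    (out / "stats_summary.json").write_text(json.dumps(summary, indent=1))
    files.append("stats_summary.json")
    manifest = {"files": sorted(files), "n_sessions": len(bundle.preprocessed)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
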