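"""End-to-end orchestration of the reversal/network-synergy analysis.

Stages, in the order of the underlying study design:

1. per-layer differential screen of model vs control and treated vs model;
2. OPLS-DA + VIP screening for the metabolite layer;
3. treatment-reversal selection per layer;
4. interactome subnetworks induced by reverted transcripts / proteins;
5. MCODE module detection per layer (labels A*, B*);
6. S_AB separation matrix and the most synergistic module pair;
7. hub ranking within the best pair;
8. optional over-representation analysis of reverted transcripts.

Everything is driven by a single validated config and a seed; rerunning
with the same config produces byte-identical outputs.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import network, reversal, screen, separation
from .ora import ora as _run_ora, read_gmt as _read_gmt
from .matrix import OmicsMatrix
from .opls import fit_oplsda, vip_criterion
from .synthetic import SyntheticSpec, generate_dataset, generate_interactome

logger = logging.getLogger(__name__)

_LAYERS = ("transcript", "protein", "metabolite")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    layers: dict  # layer -> {"matrix": path, "samples": path, "log2": bool}
    interactome: str
    outdir: str
    gmt: str | None = None
    fc_threshold: float = 1.0
    alpha: float = 0.05
    vip_threshold: float = 1.0
    n_orth: int = 1
    min_score: float | None = None
    top_k_hubs: int = 7
    seed: int = 0
    mcode: dict = field(default_factory=dict)


_KNOWN_KEYS = {
    "layers",
    "interactome",
    "outdir",
    "gmt",
    "fc_threshold",
    "alpha",
    "vip_threshold",
    "n_orth",
    "min_score",
    "top_k_hubs",
    "seed",
    "mcode",
}
_KNOWN_MCODE = {
    "degree_cutoff",
    "node_score_cutoff",
    "k_core",
    "max_depth",
    "haircut",
    "fluff",
}


def validate_config(source) -> PipelineConfig:
    """Normalize a config mapping or YAML path; collect *all* errors.

    Unknown keys are rejected (with a closest-match suggestion), paths
    must exist, thresholds must be positive, the seed an integer.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")

    errors: list[str] = []

    def _suggest(key, known):
        close = difflib.get_close_matches(key, known, n=1)
        hint = f"; did you mean {close[0]!r}?" if close else ""
        return f"unknown key {key!r}{hint}"

    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(_suggest(key, _KNOWN_KEYS))
    for key in raw.get("mcode", {}) or {}:
        if key not in _KNOWN_MCODE:
            errors.append(f"mcode: {_suggest(key, _KNOWN_MCODE)}")

    layers = raw.get("layers") or {}
    if not layers:
        errors.append("layers: at least one omics layer is required")
    for name, entry in layers.items():
        if name not in _LAYERS:
            errors.append(f"layers: {_suggest(name, _LAYERS)}")
            continue
        for req in ("matrix", "samples"):
            path = (entry or {}).get(req)
            if path is None:
                errors.append(f"layers.{name}: missing {req!r} path")
            elif not Path(path).exists():
                errors.append(f"layers.{name}.{req}: no such file {path!r}")
    if "interactome" not in raw:
        errors.append("interactome: required")
    elif not Path(raw["interactome"]).exists():
        errors.append(f"interactome: no such file {raw['interactome']!r}")
    if raw.get("gmt") is not None and not Path(raw["gmt"]).exists():
        errors.append(f"gmt: no such file {raw['gmt']!r}")
    if "outdir" not in raw:
        errors.append("outdir: required")

    for key, lo in (("fc_threshold", 0.0), ("alpha", 0.0), ("vip_threshold", 0.0)):
        if key in raw:
            try:
                if float(raw[key]) <= lo:
                    errors.append(f"{key}: must be > {lo}")
            except (TypeError, ValueError):
                errors.append(f"{key}: not a number")
    if "alpha" in raw:
        try:
            if float(raw["alpha"]) >= 1.0:
                errors.append("alpha: must be < 1")
        except (TypeError, ValueError):
            pass
    if "seed" in raw and not isinstance(raw["seed"], int):
        errors.append("seed: must be an integer")

    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))

    return PipelineConfig(
        layers={k: dict(v) for k, v in layers.items()},
        interactome=str(raw["interactome"]),
        outdir=str(raw["outdir"]),
        gmt=str(raw["gmt"]) if raw.get("gmt") is not None else None,
        fc_threshold=float(raw.get("fc_threshold", 1.0)),
        alpha=float(raw.get("alpha", 0.05)),
        vip_threshold=float(raw.get("vip_threshold", 1.0)),
        n_orth=int(raw.get("n_orth", 1)),
        min_score=(float(raw["min_score"]) if raw.get("min_score") is not None else None),
        top_k_hubs=int(raw.get("top_k_hubs", 7)),
        seed=int(raw.get("seed", 0)),
        mcode=dict(raw.get("mcode") or {}),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, state: str) -> None:
    lines = ["file\tsha256\tstate"]
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "MANIFEST.tsv":
            lines.append(f"{p.relative_to(outdir)}\t{_sha256(p)}\t{state}")
    (outdir / "MANIFEST.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write TSVs, a JSON summary, a log and a MANIFEST.

    Returns the summary dict. Any stage failure raises
    :class:`PipelineError` naming the stage; outputs produced so far are
    kept, with the MANIFEST marking the bundle as partial.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def _log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    summary: dict = {"seed": config.seed, "layers": {}}
    stage = "load"
    try:
        matrices: dict[str, OmicsMatrix] = {}
        for name, entry in config.layers.items():
            matrices[name] = OmicsMatrix.read_tsv(
                entry["matrix"],
                entry["samples"],
                layer=name,
                log2_scale=bool(entry.get("log2", True)),
            ).to_log2()
            _log(f"load: {name} {matrices[name].values.shape[0]} features, "
                 f"{matrices[name].values.shape[1]} samples")

        stage = "screen"
        reverted: dict[str, list] = {}
        for name, mat in matrices.items():
            mc = screen.screen(
                mat.restrict_groups(("model", "control")),
                ("model", "control"),
                config.fc_threshold,
                config.alpha,
            )
            tm = screen.screen(
                mat.restrict_groups(("treated", "model")),
                ("treated", "model"),
                config.fc_threshold,
                config.alpha,
            )
            if name == "metabolite":
                stage = "opls"
                m_mc = fit_oplsda(
                    mat.restrict_groups(("model", "control")),
                    n_orth=config.n_orth,
                    seed=config.seed,
                )
                m_tm = fit_oplsda(
                    mat.restrict_groups(("treated", "model")),
                    n_orth=config.n_orth,
                    seed=config.seed + 1,
                )
                mc = vip_criterion(mc, m_mc, config.vip_threshold)
                tm = vip_criterion(tm, m_tm, config.vip_threshold)
                summary["opls"] = {
                    "model_vs_control": {"r2y": m_mc.r2y, "q2": m_mc.q2},
                    "treated_vs_model": {"r2y": m_tm.r2y, "q2": m_tm.q2},
                }
                stage = "screen"
            mc.write_tsv(outdir / f"{name}_model_vs_control.tsv")
            tm.write_tsv(outdir / f"{name}_treated_vs_model.tsv")

            stage = "reversal"
            rev = reversal.find_reverted(mc, tm)
            reverted[name] = rev
            with open(outdir / f"{name}_reverted.tsv", "w", encoding="utf-8") as fh:
                fh.write(
                    "feature_id\tlog2fc_model_vs_control\tp_mc\t"
                    "log2fc_treated_vs_model\tp_tm\tdirection\n"
                )
                for r in rev:
                    fh.write(
                        f"{r.feature_id}\t{r.log2fc_mc:.6g}\t{r.p_mc:.6g}\t"
                        f"{r.log2fc_tm:.6g}\t{r.p_tm:.6g}\t{r.direction}\n"
                    )
            summary["layers"][name] = {
                "n_features": int(mat.values.shape[0]),
                "n_differential_mc": int(mc.table["significant"].sum()),
                "n_differential_tm": int(tm.table["significant"].sum()),
                "n_reverted": len(rev),
                **reversal.reversal_summary(rev),
            }
            _log(f"{name}: {summary['layers'][name]['n_differential_mc']} differential "
                 f"(model vs control), {len(rev)} reverted")
            stage = "screen"

        stage = "interactome"
        graph = network.read_edgelist(config.interactome, min_score=config.min_score)
        _log(f"interactome: {graph.number_of_nodes()} nodes, "
             f"{graph.number_of_edges()} edges")

        stage = "modules"
        module_sets: dict[str, list] = {}
        for name, prefix in (("transcript", "A"), ("protein", "B")):
            if name not in reverted:
                continue
            feats = [r.feature_id for r in reverted[name]]
            sub = network.induced_subnetwork(graph, feats)
            mods = network.mcode(sub, label_prefix=prefix, **config.mcode)
            module_sets[prefix] = mods
            network.write_modules_tsv(mods, outdir / f"{name}_modules.tsv")
            summary.setdefault("modules", {})[name] = {
                m.label: {"n_nodes": len(m.members), "score": round(m.score, 6)}
                for m in mods
            }
            _log(f"modules[{name}]: {len(mods)} detected")

        best_hubs: dict = {}
        if module_sets.get("A") and module_sets.get("B"):
            stage = "separation"
            sep = separation.separation_matrix(
                graph, module_sets["A"], module_sets["B"]
            )
            sep.s_ab.to_csv(outdir / "separation_matrix.tsv", sep="\t")
            summary["separation"] = {
                "s_ab": {
                    a: {b: round(float(sep.s_ab.at[a, b]), 6) for b in sep.s_ab.columns}
                    for a in sep.s_ab.index
                },
                "best_pair": list(sep.best_pair),
                "best_value": round(sep.best_value, 6),
                "unevaluable": sep.unevaluable,
            }
            _log(f"separation: best pair {sep.best_pair} "
                 f"S_AB={sep.best_value:.3f}")

            stage = "hubs"
            by_label = {m.label: m for m in module_sets["A"] + module_sets["B"]}
            for lab in sep.best_pair:
                hubs = network.hub_rank(graph, by_label[lab], config.top_k_hubs)
                best_hubs[lab] = hubs
            summary["hubs"] = best_hubs
            with open(outdir / "hubs.tsv", "w", encoding="utf-8") as fh:
                fh.write("module_label\trank\tnode\n")
                for lab, hubs in best_hubs.items():
                    for i, v in enumerate(hubs, 1):
                        fh.write(f"{lab}\t{i}\t{v}\n")

        if config.gmt is not None and "transcript" in reverted:
            stage = "enrichment"
            coll = _read_gmt(config.gmt)
            query = {r.feature_id for r in reverted["transcript"]}
            enr = _run_ora(query, coll)
            enr.to_csv(outdir / "enrichment_transcript.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                "top_terms": enr.head(5)[["term", "k", "K", "p", "q"]]
                .round(8)
                .to_dict(orient="records")
            }
            _log(f"enrichment: {len(enr)} sets tested")
    except Exception as exc:
        (outdir / "pipeline.log").write_text(
            "\n".join(log_lines + [f"FAILED at stage {stage}: {exc}"]) + "\n",
            encoding="utf-8",
        )
        _write_manifest(outdir, "partial")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    _write_manifest(outdir, "complete")
    return summary


# --- demo world ---------------------------------------------------------

def write_demo_inputs(dirpath, seed: int = 0) -> dict:
    """Write a complete synthetic input bundle and return a config mapping.

    Transcript and protein layers share one feature-id space (a gene and
    its protein product are the same interactome node), with the planted
    reversed sets overlapping; the interactome plants two dense blocks
    inside the transcript-reversed region so the most synergistic
    module pair has a known ground truth. The metabolite layer is
    independent and screened through OPLS-DA/VIP.
    """
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    specs = {
        "transcript": SyntheticSpec(
            n_features=300, frac_disease=0.4, frac_reversed=0.5,
            effect_log2=2.5, noise_sd=0.5, seed=seed, layer="transcript",
            feature_prefix="F",
            interactome_blocks=[(20, 0.9, 0.005), (25, 0.9, 0.005)],
        ),
        "protein": SyntheticSpec(
            n_features=300, frac_disease=0.3, frac_reversed=0.35,
            effect_log2=2.5, noise_sd=0.5, seed=seed + 1, layer="protein",
            feature_prefix="F",
        ),
        "metabolite": SyntheticSpec(
            n_features=120, frac_disease=0.4, frac_reversed=0.5,
            effect_log2=2.0, noise_sd=0.5, seed=seed + 2, layer="metabolite",
            feature_prefix="M",
        ),
    }
    layers = {}
    truths = {}
    for name, spec in specs.items():
        mat, truth = generate_dataset(spec)
        mpath = dirpath / f"{name}_matrix.tsv"
        spath = dirpath / f"{name}_samples.tsv"
        mat.write_tsv(mpath, spath)
        layers[name] = {"matrix": str(mpath), "samples": str(spath), "log2": True}
        truths[name] = truth

    feature_ids = list(truths["transcript"].index)
    graph = generate_interactome(specs["transcript"], feature_ids)
    gpath = dirpath / "interactome.tsv"
    network.write_edgelist(graph, gpath)

    rng_sets = np.random.default_rng(seed + 3)
    gmt_path = dirpath / "sets.gmt"
    with open(gmt_path, "w", encoding="utf-8") as fh:
        fh.write("planted_block_1\tplanted\t" + "\t".join(feature_ids[:20]) + "\n")
        fh.write("planted_block_2\tplanted\t" + "\t".join(feature_ids[20:45]) + "\n")
        for i in range(3):
            members = sorted(rng_sets.choice(feature_ids, size=30, replace=False))
            fh.write(f"random_set_{i + 1}\trandom\t" + "\t".join(members) + "\n")

    return {
        "layers": layers,
        "interactome": str(gpath),
        "gmt": str(gmt_path),
        "outdir": str(dirpath / "results"),
        "seed": seed,
    }
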