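"""End-to-end orchestration: preprocessing, candidate runs, reporting.

A full experiment repeats, over Monte-Carlo train/test splits: record
standardization bounds via single-objective pretraining, train K Pareto
candidates (Pareto MTL subproblems or a scalarization λ-grid) plus the two
extreme points, evaluate every candidate on both splits, and compute front
metrics (percentage / hypervolume / NDC) and the surrogate metric table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .front import (
    hypervolume2d,
    ndc,
    percentage_nondominated,
    shared_grid,
    shared_reference_point,
    surrogate_trade_off_table,
)
from .mopt import (
    TrainConfig,
    evaluate_candidate,
    record_bounds,
    train_candidate,
    train_extremes,
)
from .simulate import SimSpec, simulate_zinb_dataset
from .vae import compute_library_prior

logger = logging.getLogger(__name__)

__all__ = ["RawSource", "ExperimentConfig", "preprocess", "run_experiment",
           "export_report"]


@dataclasses.dataclass
class RawSource:
    """One raw count matrix before integration."""

    counts: np.ndarray
    gene_names: np.ndarray
    cell_type: np.ndarray | None = None
    gene_lengths: np.ndarray | None = None
    normalize_gene_length: bool = False
    apply_cell_filter: bool = True


def preprocess(sources: list[RawSource], *, min_total: int = 100
               ) -> ExpressionDataset:
    """Integrate raw sources into one dataset, assigning batch by source.

    Per source, in order: optional gene-length standardization (counts
    divided by length relative to the median length, rounded back to
    integers); removal of cells with total count ≤ ``min_total`` (when
    enabled for the source); gene selection by positive mean of the
    unit-variance-scaled matrix — the scaling is used *only* for this
    selection statistic, raw counts are retained for the likelihood.
    Sources are then concatenated on the intersection of their gene names.
    """
    if not sources:
        raise ValueError("need at least one raw source")
    kept = []
    for si, src in enumerate(sources):
        counts = np.asarray(src.counts)
        names = np.asarray(src.gene_names, dtype=object)
        if names.size != counts.shape[1] or any(
            nm is None or str(nm) == "" for nm in names
        ):
            raise ValueError(f"source {si} is missing gene names")
        if src.normalize_gene_length:
            if src.gene_lengths is None:
                raise ValueError(f"source {si} has no gene lengths to normalize by")
            lengths = np.asarray(src.gene_lengths, dtype=np.float64)
            counts = np.rint(
                counts / (lengths / np.median(lengths))[None, :]
            ).astype(np.int64)
        if src.apply_cell_filter:
            keep_cells = counts.sum(axis=1) > min_total
            counts = counts[keep_cells]
            ct = None if src.cell_type is None else np.asarray(src.cell_type)[keep_cells]
        else:
            ct = None if src.cell_type is None else np.asarray(src.cell_type)
        # positive-mean selection on the unit-variance-scaled matrix; the
        # sign of the scaled mean equals the sign of the raw mean
        x = counts.astype(np.float64)
        sd = x.std(axis=0, ddof=0)
        scaled_mean = np.where(sd > 0, x.mean(axis=0) / np.where(sd > 0, sd, 1.0),
                               x.mean(axis=0))
        keep_genes = scaled_mean > 0
        kept.append((counts[:, keep_genes], names[keep_genes], ct))

    common = set(kept[0][1].tolist())
    for _, names, _ in kept[1:]:
        common &= set(names.tolist())
    if not common:
        raise ValueError("gene-name intersection across sources is empty")
    order = [nm for nm in kept[0][1].tolist() if nm in common]

    blocks, batches, cts = [], [], []
    have_ct = all(ct is not None for _, _, ct in kept)
    for si, (counts, names, ct) in enumerate(kept):
        pos = {nm: i for i, nm in enumerate(names.tolist())}
        cols = [pos[nm] for nm in order]
        blocks.append(counts[:, cols])
        batches.append(np.full(counts.shape[0], si, dtype=np.int64))
        if have_ct:
            cts.append(ct)
    return ExpressionDataset(
        counts=np.vstack(blocks),
        batch=np.concatenate(batches),
        gene_names=np.asarray(order, dtype=object),
        cell_type=np.concatenate(cts) if have_ct else None,
    )


@dataclasses.dataclass
class ExperimentConfig:
    """One front-estimation experiment (dataset × method × measure)."""

    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    method: str = "pareto_mtl"           # or "scalarization"
    repetitions: int = 1
    split_fraction: float = 0.9
    seed: int = 0
    sim: SimSpec | None = None           # used when no dataset is supplied
    compute_surrogates: bool = True

    def __post_init__(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must lie in (0,1)")
        if self.method not in ("pareto_mtl", "scalarization"):
            raise ValueError("method must be pareto_mtl or scalarization")


def _front_metrics(points: np.ndarray) -> dict:
    ref = shared_reference_point(points)
    mu, origin = shared_grid(points)
    return {
        "percentage": percentage_nondominated(points),
        "hypervolume": hypervolume2d(points, ref),
        "ndc": ndc(points, mu, origin),
        "reference": ref.tolist(),
        "ndc_mu": mu,
        "ndc_origin": origin.tolist(),
    }


def run_repetition(ds: ExpressionDataset, cfg: ExperimentConfig, rep: int
                   ) -> dict:
    """One Monte-Carlo split: bounds, K candidates + 2 extremes, evaluation."""
    tc = dataclasses.replace(cfg.train, seed=cfg.seed + rep)
    split = ds.make_split(cfg.split_fraction, seed=cfg.seed + rep)
    train_ds, test_ds = split.train_subset(), split.test_subset()
    prior = compute_library_prior(train_ds)

    logger.info("rep %d: recording standardization bounds", rep)
    bounds, u_model, v_models = record_bounds(train_ds, tc, prior=prior)
    u_ext, v_ext = train_extremes(train_ds, tc, prior=prior,
                                  pretrained=(u_model, v_models))

    candidates = []
    failures = []
    for j in range(tc.K):
        try:
            if cfg.method == "pareto_mtl":
                logger.info("rep %d: Pareto MTL subproblem %d/%d", rep, j + 1, tc.K)
                cand = train_candidate(train_ds, tc, bounds,
                                       method="pareto_mtl", k=j, prior=prior)
            else:
                lam = (j + 1) / (tc.K + 1)
                logger.info("rep %d: scalarization lambda=%.3f", rep, lam)
                cand = train_candidate(train_ds, tc, bounds,
                                       method="scalarization", lam=lam,
                                       prior=prior)
            candidates.append(cand)
        except FloatingPointError as exc:   # candidate failure is recorded
            logger.error("rep %d: candidate %d failed: %s", rep, j, exc)
            failures.append({"candidate": j, "error": str(exc)})
    all_cands = [v_ext] + candidates + [u_ext]

    rows = []
    latents = {}
    for i, cand in enumerate(all_cands):
        for split_name, dsx in (("train", train_ds), ("test", test_ds)):
            u, v, ub, vb = evaluate_candidate(
                cand, dsx, tc, bounds, prior, split=split_name,
                seed=cfg.seed + 10000 * rep + i)
            rows.append({"candidate": cand.tag, "index": i, "split": split_name,
                         "U": u, "V": v, "U_bar": ub, "V_bar": vb})
        latents[cand.tag] = cand.vae.latent_mean(test_ds.counts)
    table = pd.DataFrame(rows)

    fronts = {}
    for split_name in ("train", "test"):
        sub = table[table.split == split_name]
        pts = sub[["U_bar", "V_bar"]].to_numpy()
        fronts[split_name] = _front_metrics(pts)
        fronts[split_name]["n_candidates"] = int(len(sub))

    result = {
        "rep": rep,
        "bounds": dataclasses.asdict(bounds),
        "objectives": table,
        "fronts": fronts,
        "failures": failures,
        "partial": bool(failures),
        "latents": latents,
        "seed": cfg.seed + rep,
    }
    if cfg.compute_surrogates and test_ds.cell_type is not None:
        sub = table[table.split == "test"].set_index("candidate")
        tags = [c.tag for c in all_cands]
        result["surrogates"] = surrogate_trade_off_table(
            tags, [latents[t] for t in tags], test_ds.batch, test_ds.cell_type,
            [sub.loc[t, "U_bar"] for t in tags],
            seed=cfg.seed + rep,
            be_kwargs={"n_neighbors": min(50, max(5, test_ds.n_cells // 10)),
                       "n_pools": 10, "pool_size": min(100, test_ds.n_cells)},
        )
    return result


def run_experiment(cfg: ExperimentConfig, ds: ExpressionDataset | None = None
                   ) -> dict:
    """All repetitions plus the mean ± SD aggregate of the front metrics."""
    if ds is None:
        if cfg.sim is None:
            raise ValueError("supply a dataset or a simulation spec")
        ds, _ = simulate_zinb_dataset(cfg.sim)
    reps = [run_repetition(ds, cfg, rep) for rep in range(cfg.repetitions)]
    aggregate = {}
    for split_name in ("train", "test"):
        for metric in ("percentage", "hypervolume", "ndc"):
            vals = np.array([r["fronts"][split_name][metric] for r in reps],
                            dtype=np.float64)
            aggregate[f"{split_name}_{metric}"] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
    return {"config_method": cfg.method, "measure": cfg.train.measure,
            "repetitions": reps, "aggregate": aggregate}


def export_report(results: dict, outdir: str | Path) -> None:
    """Write JSON metrics, CSV fronts and latent coordinates per repetition."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    meta = {
        "method": results["config_method"],
        "measure": results["measure"],
        "aggregate": results["aggregate"],
        "partial_repetitions": [r["rep"] for r in results["repetitions"]
                                if r["partial"]],
        "repetitions": [],
    }
    for r in results["repetitions"]:
        rep_dir = outdir / f"rep_{r['rep']}"
        rep_dir.mkdir(exist_ok=True)
        tab: pd.DataFrame = r["objectives"]
        tab.to_csv(rep_dir / "objectives.csv", index=False)
        for split_name in ("train", "test"):
            sub = tab[tab.split == split_name]
            front = sub[["candidate", "U_bar", "V_bar"]].copy()
            from .front import nondominated_mask

            front["dominated"] = ~nondominated_mask(
                sub[["U_bar", "V_bar"]].to_numpy())
            front.columns = ["candidate_id", "obj1", "obj2", "dominated"]
            front.to_csv(rep_dir / f"front_{split_name}.csv", index=False)
        for tag, z in r["latents"].items():
            safe = tag.replace("=", "_").replace(".", "p")
            np.savetxt(rep_dir / f"latent_{safe}.csv", z, delimiter=",")
        if "surrogates" in r:
            r["surrogates"].to_csv(rep_dir / "surrogates.csv")
        meta["repetitions"].append({
            "rep": r["rep"], "seed": r["seed"], "bounds": r["bounds"],
            "fronts": r["fronts"], "failures": r["failures"],
            "partial": r["partial"],
        })
    (outdir / "report.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    logger.info("report written to %s", outdir)
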