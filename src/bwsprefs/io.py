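"""Plain-text file formats: catalogs, designs, responses, scores, results.

Everything is delimited text with headers — the domain has no binary
standard to honor, and transparency wins.  Designs carry a comment header
recording (v, b, k, r, lam) and the canonical item order so a file round-
trips exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .design import BIBDesign, Questionnaire, build_questionnaire
from .items import ChoiceItem
from .model import ComparisonTable, MaxDiffResults
from .scoring import CountScore, rank_items
from .simulate import ResponseSet, StudyDataset

RESPONSE_COLUMNS = ["respondent_id", "phase", "block_id", "best_item_id", "worst_item_id"]


# ---- catalogs -------------------------------------------------------

def write_catalog(path, catalog: Sequence[ChoiceItem]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["item_id", "label", "description", "is_quick_variant"])
        for item in catalog:
            w.writerow([item.item_id, item.label, item.description,
                        int(item.is_quick_variant)])


def read_catalog(path) -> tuple[ChoiceItem, ...]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    return tuple(
        ChoiceItem(r.item_id, r.label, r.description,
                   bool(int(r.is_quick_variant or 0)))
        for r in df.itertuples()
    )


# ---- designs --------------------------------------------------------

def write_design(path, design: BIBDesign, item_ids: Sequence[str]) -> None:
    """One block per record; blocks reference stable item-id tokens."""
    if len(item_ids) != design.v:
        raise ValueError("item_ids length does not match design.v")
    with open(path, "w", newline="") as fh:
        fh.write(f"# bwsprefs-design version={__version__} "
                 f"v={design.v} b={design.b} k={design.k} r={design.r} lam={design.lam}\n")
        fh.write("# items=" + ",".join(item_ids) + "\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["block_id", "item_ids"])
        for bi, blk in enumerate(design.blocks):
            w.writerow([bi, ",".join(item_ids[i] for i in blk)])


def read_design(path) -> tuple[BIBDesign, tuple[str, ...]]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header.startswith("# bwsprefs="):  # provenance stamp from a pipeline run
            header = fh.readline().strip()
        items_line = fh.readline().strip()
    if not header.startswith("# bwsprefs-design"):
        raise ValueError(f"{path} is not a bwsprefs design file")
    meta = dict(tok.split("=", 1) for tok in header.split()[2:])
    item_ids = tuple(items_line.removeprefix("# items=").split(","))
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    idx = {iid: i for i, iid in enumerate(item_ids)}
    blocks = tuple(
        tuple(sorted(idx[t] for t in row.item_ids.split(",")))
        for row in df.itertuples()
    )
    design = BIBDesign(
        v=int(meta["v"]), b=int(meta["b"]), k=int(meta["k"]),
        r=int(meta["r"]), lam=int(meta["lam"]), blocks=blocks,
    )
    return design, item_ids


# ---- responses ------------------------------------------------------

def responses_to_frame(dataset: StudyDataset) -> pd.DataFrame:
    """Long format, one row per block; missing picks as empty fields."""
    rows = []
    for resp in dataset.responses:
        for bi in sorted(resp.picks):
            pick = resp.picks[bi]
            best, worst = pick if pick is not None else ("", "")
            rows.append((resp.respondent_id, resp.phase, bi, best, worst))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def responses_from_frame(df: pd.DataFrame, questionnaire: Questionnaire) -> StudyDataset:
    missing_cols = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"response table lacks columns {missing_cols}")
    responses = []
    for rid, grp in df.groupby("respondent_id", sort=False):
        phase = str(grp["phase"].iloc[0])
        picks: dict[int, tuple[str, str] | None] = {
            bi: None for bi in range(questionnaire.design.b)
        }
        for row in grp.itertuples():
            best = "" if pd.isna(row.best_item_id) else str(row.best_item_id)
            worst = "" if pd.isna(row.worst_item_id) else str(row.worst_item_id)
            picks[int(row.block_id)] = (best, worst) if best and worst else None
        responses.append(ResponseSet(str(rid), phase, picks))
    return StudyDataset(questionnaire, responses)


def write_responses(path, dataset: StudyDataset) -> None:
    responses_to_frame(dataset).to_csv(path, index=False)


def read_responses(path, questionnaire: Questionnaire) -> StudyDataset:
    df = pd.read_csv(path, comment="#",
                     dtype={"respondent_id": str, "phase": str, "block_id": int})
    return responses_from_frame(df, questionnaire)


# ---- scores and results ---------------------------------------------

def scores_to_frame(scores: Sequence[CountScore]) -> pd.DataFrame:
    ranked = rank_items(scores)
    rank_of = {s.item_id: i + 1 for i, s in enumerate(ranked)}
    return pd.DataFrame(
        [
            (s.item_id, s.n_best, s.n_worst, s.bw, s.availability,
             s.standardized, rank_of[s.item_id])
            for s in scores
        ],
        columns=["item_id", "n_best", "n_worst", "bw", "availability",
                 "standardized", "rank"],
    ).sort_values("rank").reset_index(drop=True)


def write_scores(path, scores: Sequence[CountScore]) -> None:
    scores_to_frame(scores).to_csv(path, index=False)


def write_results(path, results: MaxDiffResults | Mapping[str, MaxDiffResults]) -> None:
    """Fit results as delimited text: one row per (subgroup, item)."""
    if isinstance(results, MaxDiffResults):
        frames = [results.to_frame()]
    else:
        frames = [results[k].to_frame() for k in results]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_comparison(path, table: ComparisonTable) -> None:
    with open(path, "w") as fh:
        fh.write("# top ranked items per subgroup\n")
        table.top.to_csv(fh)
        fh.write("# beta trajectories per item\n")
        table.trajectories.to_csv(fh, float_format="%.6f")


def write_plot_data(path, results: MaxDiffResults) -> None:
    """Forest-plot data: beta with CI bounds, sorted descending."""
    df = results.to_frame()[["item_id", "beta", "se", "ci_low", "ci_high"]]
    df.to_csv(path, index=False, float_format="%.6f")
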