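"""Two-caller consensus for CG methylation via a small decision-tree ensemble.

Per-read scores from the LLR caller (mapped to [0, 1] by the logistic
function) and the probability caller are paired by (site, read) and combined
either by a Random Forest with 3 trees of depth <= 10 — the configuration the
consensus approach was optimized at — trained on labeled synthetic pairs, or
by a model-free mean-score rule. Consensus is defined for the CG context only;
CHG/CHH rely on the probability caller alone.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .calls import AMBIGUOUS, CALL_COLUMNS, METHYLATED, UNMETHYLATED, aggregate_site_frequency

logger = logging.getLogger(__name__)

SITE_KEY = ["sequence_id", "pos", "strand"]
PAIR_KEY = SITE_KEY + ["read_id"]

#: Fixed feature order fed to the ensemble.
FEATURES = ["score_llr_normalized", "score_prob"]


def normalize_llr(llr):
    """Map a log-likelihood ratio to [0, 1] with the logistic function.

    Monotone increasing, parameter-free and invertible; 0 maps to 0.5.
    """
    return 1.0 / (1.0 + np.exp(-np.asarray(llr, dtype=float)))


def _dedupe(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep one call per (site, read): the most confident (largest |score-0.5|
    after normalization), warning when duplicates are found."""
    dup = calls.duplicated(PAIR_KEY, keep=False)
    if not dup.any():
        return calls
    logger.warning(
        "%d duplicate (site, read) calls in one source; keeping most confident",
        int(dup.sum()),
    )
    score = calls["raw_score"].to_numpy(float)
    if (calls["source"] == "llr_caller").any():
        conf = np.abs(normalize_llr(score) - 0.5)
    else:
        conf = np.abs(score - 0.5)
    order = np.argsort(-conf, kind="stable")
    deduped = calls.iloc[order].drop_duplicates(PAIR_KEY, keep="first")
    return deduped.sort_index()


def pair_reads(
    llr_calls: pd.DataFrame, prob_calls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join the two call sets on (site key, read id).

    Returns ``(pairs, fallback)`` where ``pairs`` has the normalized LLR score
    and the probability score per shared read, and ``fallback`` collects the
    unpaired calls from both sources (original call columns preserved).
    """
    llr_calls = _dedupe(llr_calls)
    prob_calls = _dedupe(prob_calls)
    left = llr_calls.rename(columns={"raw_score": "llr"})[PAIR_KEY + ["llr", "call"]]
    right = prob_calls.rename(columns={"raw_score": "score_prob"})[
        PAIR_KEY + ["score_prob", "call"]
    ]
    merged = left.merge(
        right, on=PAIR_KEY, how="outer", suffixes=("_llr", "_prob"), indicator=True
    )
    both = merged["_merge"] == "both"
    pairs = merged.loc[both, PAIR_KEY].copy()
    pairs["score_llr_normalized"] = normalize_llr(merged.loc[both, "llr"].to_numpy())
    pairs["score_prob"] = merged.loc[both, "score_prob"].to_numpy()

    fb_llr = merged[merged["_merge"] == "left_only"]
    fb_prob = merged[merged["_merge"] == "right_only"]
    fallback = pd.concat(
        [
            pd.DataFrame(
                {
                    **{k: fb_llr[k] for k in PAIR_KEY},
                    "source": "llr_caller",
                    "raw_score": fb_llr["llr"],
                    "call": fb_llr["call_llr"],
                }
            ),
            pd.DataFrame(
                {
                    **{k: fb_prob[k] for k in PAIR_KEY},
                    "source": "prob_caller",
                    "raw_score": fb_prob["score_prob"],
                    "call": fb_prob["call_prob"],
                }
            ),
        ],
        ignore_index=True,
    )
    logger.info("paired %d reads, %d unpaired routed to fallback", len(pairs), len(fallback))
    return pairs.reset_index(drop=True), fallback


@dataclass
class ConsensusModel:
    """A trained consensus ensemble plus its training metadata."""

    forest: RandomForestClassifier
    seed: int
    n_training_pairs: int
    training_accuracy: float
    n_trees: int = 3
    max_depth: int = 10
    features: tuple[str, ...] = tuple(FEATURES)

    def predict(self, pairs: pd.DataFrame) -> np.ndarray:
        """Deterministic per-read consensus calls for paired scores."""
        x = pairs[list(self.features)].to_numpy(float)
        pred = self.forest.predict(x)
        return np.where(pred == 1, METHYLATED, UNMETHYLATED)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self.forest, fh)
        meta = {
            "seed": self.seed,
            "n_training_pairs": self.n_training_pairs,
            "training_accuracy": self.training_accuracy,
            "n_trees": self.n_trees,
            "max_depth": self.max_depth,
            "features": list(self.features),
            "format_version": 1,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def train_consensus(
    labeled_pairs: pd.DataFrame,
    n_trees: int = 3,
    max_depth: int = 10,
    seed: int = 0,
) -> ConsensusModel:
    """Train the consensus ensemble on labeled pairs.

    ``labeled_pairs`` must carry the two feature columns and a boolean/0-1
    ``label`` column (1 = methylated). Both classes must be present. Training
    is deterministic under ``seed``.
    """
    y = labeled_pairs["label"].to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class; both are required")
    x = labeled_pairs[FEATURES].to_numpy(float)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed
    )
    forest.fit(x, y)
    acc = float((forest.predict(x) == y).mean())
    logger.info("consensus ensemble trained on %d pairs, training accuracy %.4f", len(y), acc)
    return ConsensusModel(
        forest=forest,
        seed=seed,
        n_training_pairs=len(y),
        training_accuracy=acc,
        n_trees=n_trees,
        max_depth=max_depth,
    )


def rule_consensus(pairs: pd.DataFrame) -> np.ndarray:
    """Model-free consensus: mean of the two [0, 1] scores, thresholded at 0.5.

    An exact tie is ambiguous.
    """
    mean = (
        pairs["score_llr_normalized"].to_numpy(float)
        + pairs["score_prob"].to_numpy(float)
    ) / 2.0
    call = np.full(len(pairs), AMBIGUOUS, dtype=object)
    call[mean > 0.5] = METHYLATED
    call[mean < 0.5] = UNMETHYLATED
    return call


def consensus_calls(
    pairs: pd.DataFrame, model: ConsensusModel | None = None
) -> pd.DataFrame:
    """Per-read consensus calls for paired reads (model if given, else rule)."""
    out = pairs[PAIR_KEY].copy()
    out["source"] = "consensus"
    out["raw_score"] = (
        pairs["score_llr_normalized"].to_numpy(float)
        + pairs["score_prob"].to_numpy(float)
    ) / 2.0
    out["call"] = model.predict(pairs) if model is not None else rule_consensus(pairs)
    return out[CALL_COLUMNS]


def consensus_site_frequency(
    consensus: pd.DataFrame,
    fallback: pd.DataFrame,
    context_index: pd.DataFrame,
    min_coverage: int = 5,
    fallback_policy: str = "single",
) -> pd.DataFrame:
    """Aggregate consensus (and optionally fallback single-caller) calls.

    ``fallback_policy`` "single" keeps each unpaired read's own caller call;
    "drop" discards unpaired reads. Aggregation is identical to the
    single-caller path.
    """
    if fallback_policy not in ("single", "drop"):
        raise ValueError(f"unknown fallback policy {fallback_policy!r}")
    frames = [consensus]
    if fallback_policy == "single" and len(fallback):
        frames.append(fallback[CALL_COLUMNS])
    all_calls = pd.concat(frames, ignore_index=True)
    return aggregate_site_frequency(all_calls, context_index, min_coverage=min_coverage)
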