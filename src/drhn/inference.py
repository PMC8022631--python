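"""Runtime posture recognition: prediction, confidence gate, majority voting.

The runtime loop predicts a posture path for each incoming frame sequence,
flags low-confidence predictions (combined path confidence below 40%) and
re-analyzes them by also descending the runner-up root branch, then smooths
the per-frame stream by majority voting over the last 10 leaf labels.
Voting trades responsiveness for stability: a genuine posture change
propagates to the voted output within at most 10 frames.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .hierarchy import (
    PostureTree,
    PredictedPath,
    decode_prediction,
)
from .model import DRHN

__all__ = ["VotingBuffer", "predict", "gated_predict", "vote", "StreamingSession"]


class VotingBuffer:
    """Sliding window of the most recent leaf labels (capacity 10 by default)."""

    def __init__(self, capacity: int = 10):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.window: deque[str] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self.window)


def _as_batch(seq: np.ndarray, model: DRHN) -> np.ndarray:
    frames = np.asarray(getattr(seq, "frames", seq), dtype=np.float32)
    if frames.ndim != 4:
        raise ValueError(f"expected a [t, H, W, C] sequence, got {frames.shape}")
    return frames[None]


def predict(model: DRHN, tree: PostureTree, seq: np.ndarray) -> PredictedPath:
    """Forward pass + greedy tree descent for one frame sequence."""
    scores = model.forward(_as_batch(seq, model))[0]
    return decode_prediction(tree, scores)


def _descend_from(tree: PostureTree, scores: np.ndarray, root) -> PredictedPath:
    """Greedy descent constrained to start at a given root branch."""
    path = [root]
    level = root.children
    while level:
        best = level[int(np.argmax([scores[n.index] for n in level]))]
        path.append(best)
        level = best.children
    vals = [float(scores[n.index]) for n in path]
    return PredictedPath(
        nodes=[n.name for n in path],
        leaf=path[-1].name,
        root_branch=path[0].branch_label,
        per_node_scores=vals,
        combined_confidence=float(np.mean(vals)),
    )


def gated_predict(
    model: DRHN,
    tree: PostureTree,
    seq: np.ndarray,
    threshold: float = 0.40,
) -> tuple[PredictedPath, bool]:
    """Prediction with the low-confidence gate and re-analysis.

    If the combined path confidence falls below ``threshold``, the runner-up
    root branch is also descended and the candidate with the higher combined
    confidence is returned, still flagged as low confidence.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    scores = model.forward(_as_batch(seq, model))[0]
    best = decode_prediction(tree, scores)
    if best.combined_confidence >= threshold or len(tree.roots) < 2:
        return best, False
    root_scores = [scores[r.index] for r in tree.roots]
    order = np.argsort(root_scores)[::-1]
    second = _descend_from(tree, scores, tree.roots[int(order[1])])
    chosen = second if second.combined_confidence > best.combined_confidence else best
    return chosen, True


def vote(buffer: VotingBuffer, new_leaf: str, tree: PostureTree | None = None
         ) -> tuple[VotingBuffer, str]:
    """Append a label and return the modal label of the window.

    Ties break toward the most recently seen among the tied labels,
    favouring the current posture.  With fewer than ``capacity`` entries the
    vote runs over what is available.
    """
    if tree is not None and new_leaf not in tree.leaf_names:
        raise ValueError(f"unknown leaf label: {new_leaf!r}")
    buffer.window.append(new_leaf)
    counts: dict[str, int] = {}
    for lbl in buffer.window:
        counts[lbl] = counts.get(lbl, 0) + 1
    top = max(counts.values())
    for lbl in reversed(buffer.window):  # most recent tied label wins
        if counts[lbl] == top:
            return buffer, lbl
    raise AssertionError("unreachable: window is non-empty")


class StreamingSession:
    """Stateful frame-by-frame recognizer.

    Consumes single RGB-D frames, maintains the trailing frame window (up to
    the model's maximum sequence length) and the voting buffer, and emits a
    ``(raw_path, voted_leaf, low_confidence)`` tuple per frame.
    """

    def __init__(
        self,
        model: DRHN,
        tree: PostureTree,
        vote_window: int = 10,
        threshold: float = 0.40,
    ):
        self.model = model
        self.tree = tree
        self.threshold = threshold
        self._frames: deque[np.ndarray] = deque(
            maxlen=model.config.max_sequence_len
        )
        self._buffer = VotingBuffer(vote_window)

    def push_frame(self, frame: np.ndarray) -> tuple[PredictedPath, str, bool]:
        self._frames.append(np.asarray(frame, dtype=np.float32))
        seq = np.stack(self._frames)
        path, flagged = gated_predict(
            self.model, self.tree, seq, threshold=self.threshold
        )
        self._buffer, voted = vote(self._buffer, path.leaf)
        return path, voted, flagged
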