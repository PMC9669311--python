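"""The SVM object-detection task.

A linear-kernel SVM is trained to report whether an image shows the target
object, from the responses of a chosen unit subset (viewpoint-invariant,
all viewpoint-specific, front-view-preferring specific, non-selective, or
every unit in the layer).  Thirty target and thirty non-target identities
are split 40/20 (20+20 train, 10+10 test) at the identity level; under the
front-view training regime ("train2") the training responses come from
front-view renders while the test responses come from renders within the
configured viewpoint variation range.  Features are z-scored per unit on
the training fold; subset sizes are equalized by random subsampling so
decoding differences are not dimensionality artifacts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CHANCE_LEVEL = 0.5


@dataclass
class TaskConfig:
    regime: str = "train2"            # train1 (varied) | train2 (front view)
    unit_subset: str = "invariant"
    n_target: int = 30
    n_nontarget: int = 30
    n_train: int = 40                 # identities used for training (20+20)
    n_test: int = 20                  # held-out identities (10+10)
    test_variation_range: float = 180.0
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_train + self.n_test != self.n_target + self.n_nontarget:
            raise ValueError("split counts must sum to the image count")


@dataclass
class TaskResult:
    config: TaskConfig
    accuracies: np.ndarray
    subset_size: int = 0
    chance: float = CHANCE_LEVEL

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 \
            else 0.0


def equalize_subsets(subsets: dict[str, np.ndarray],
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Subsample every unit subset to the size of the smallest one."""
    sizes = {k: len(v) for k, v in subsets.items()}
    if min(sizes.values()) == 0:
        empty = [k for k, n in sizes.items() if n == 0]
        raise ValueError(f"empty unit subset(s): {empty}")
    m = min(sizes.values())
    return {k: rng.choice(np.asarray(v), size=m, replace=False)
            for k, v in subsets.items()}


def run_task(train_responses: np.ndarray, test_responses: np.ndarray,
             image_labels: np.ndarray, unit_idx: np.ndarray,
             config: TaskConfig) -> TaskResult:
    """Run the detection task for one unit subset.

    ``train_responses`` and ``test_responses`` are (n_units, n_images)
    matrices over the *same* image identities (columns aligned): training
    uses the regime's renders (front-view for train2), testing the varied
    renders.  ``image_labels`` is a boolean vector, True for target images.
    Per repeat, identities are split stratified into train/test folds; a
    fold that comes out single-class is resampled.
    """
    unit_idx = np.asarray(unit_idx)
    if unit_idx.size == 0:
        raise ValueError("empty unit subset")
    y = np.asarray(image_labels, bool)
    n_img = len(y)
    if train_responses.shape[1] != n_img or test_responses.shape[1] != n_img:
        raise ValueError("label vector must match response columns")
    rng = np.random.default_rng(config.seed)
    tgt = np.nonzero(y)[0]
    non = np.nonzero(~y)[0]
    n_tr_t = config.n_train // 2
    accs = []
    for _ in range(config.n_repeats):
        for _attempt in range(10):
            tr = np.concatenate([rng.choice(tgt, n_tr_t, replace=False),
                                 rng.choice(non, config.n_train - n_tr_t,
                                            replace=False)])
            te = np.setdiff1d(np.arange(n_img), tr)
            if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
                break
        Xtr = train_responses[np.ix_(unit_idx, tr)].T
        Xte = test_responses[np.ix_(unit_idx, te)].T
        scaler = StandardScaler().fit(Xtr)
        # constant units on the fold get unit scale from StandardScaler
        clf = SVC(kernel="linear").fit(scaler.transform(Xtr), y[tr])
        accs.append(float(clf.score(scaler.transform(Xte), y[te])))
    return TaskResult(config, np.asarray(accs), subset_size=int(unit_idx.size))


def sweep_variation_range(train_responses: np.ndarray,
                          test_responses_by_range: dict[float, np.ndarray],
                          image_labels: np.ndarray,
                          unit_subsets: dict[str, np.ndarray],
                          config: TaskConfig,
                          equalize: bool = True) -> dict[str, dict[float, TaskResult]]:
    """Accuracy-vs-viewpoint-variation-range curves per unit subset."""
    rng = np.random.default_rng(config.seed)
    subsets = equalize_subsets(unit_subsets, rng) if equalize else unit_subsets
    out: dict[str, dict[float, TaskResult]] = {}
    for name, idx in subsets.items():
        out[name] = {}
        for V, test_resp in sorted(test_responses_by_range.items()):
            cfg = TaskConfig(**{**config.__dict__,
                                "unit_subset": name,
                                "test_variation_range": float(V),
                                "seed": (config.seed
                                         + zlib.crc32(f"{name}:{V}".encode()))
                                        % 2**31})
            out[name][float(V)] = run_task(train_responses, test_resp,
                                           image_labels, idx, cfg)
    return out
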