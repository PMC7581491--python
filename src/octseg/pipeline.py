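"""End-to-end inference: preprocess, network, graph search.

Implements the two fold-combination strategies: the *average* path runs
boundary delineation per fold network and averages the boundary-error
tables, while the *ensemble* path majority-votes the fold label maps per
scan and delineates boundaries once on the voted map.
"""

from __future__ import annotations

import numpy as np

from .graphsearch import extract_boundaries
from .metrics import aggregate_boundary_errors
from .preprocess import enhance_contrast, pad_top
from .train import TrainConfig, average_fold_errors, majority_vote


def preprocess_scan(bscan, train_cfg: TrainConfig) -> np.ndarray:
    """Network-ready image on the [0, 1] scale (enhanced + padded)."""
    px = bscan.pixels
    if train_cfg.enhance:
        px = enhance_contrast(px, train_cfg.enhance_exponent)
    px = pad_top(px, None, train_cfg.pad_rows)
    return px.astype(np.float32) / 255.0


def predict_probmaps(net, bscans, train_cfg: TrainConfig,
                     batch_size: int = 3) -> list:
    """Per-scan (3, H+pad, W) class probability maps."""
    imgs = [preprocess_scan(b, train_cfg) for b in bscans]
    out = []
    for i in range(0, len(imgs), batch_size):
        probs = net.predict_proba(np.stack(imgs[i:i + batch_size]))
        out.extend(probs[j] for j in range(probs.shape[0]))
    return out


def predict_boundaries(net, bscans, train_cfg: TrainConfig) -> list:
    """Single-network prediction: graph search on each probability map."""
    return [extract_boundaries(p, pad_rows=train_cfg.pad_rows)
            for p in predict_probmaps(net, bscans, train_cfg)]


def predict_boundaries_ensemble(nets, bscans, train_cfg: TrainConfig) -> list:
    """Ensemble prediction: per-pixel majority vote over the fold
    networks' label maps, then one graph search on the voted map."""
    per_net = [predict_probmaps(net, bscans, train_cfg) for net in nets]
    results = []
    for s in range(len(bscans)):
        probs = [per_net[k][s] for k in range(len(nets))]
        labels = [p.argmax(axis=0) for p in probs]
        voted = majority_vote(labels, prob_maps=probs)
        results.append(extract_boundaries(voted, pad_rows=train_cfg.pad_rows))
    return results


def evaluate_average_path(nets, volumes, train_cfg: TrainConfig):
    """Boundary errors of each fold network, then the fold-averaged table.

    ``volumes``: list of VolumeRecord. Returns (per-fold tables, averaged).
    """
    tables = []
    for net in nets:
        pairs = []
        for vol in volumes:
            preds = predict_boundaries(net, vol.bscans, train_cfg)
            pairs.extend(zip(preds, vol.boundaries))
        tables.append(aggregate_boundary_errors(pairs, method="average"))
    return tables, average_fold_errors(tables)


def evaluate_ensemble_path(nets, volumes, train_cfg: TrainConfig):
    """Boundary errors of the majority-voted ensemble prediction."""
    pairs = []
    for vol in volumes:
        preds = predict_boundaries_ensemble(nets, vol.bscans, train_cfg)
        pairs.extend(zip(preds, vol.boundaries))
    return aggregate_boundary_errors(pairs, method="ensemble")
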