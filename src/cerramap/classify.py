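"""Two-stage hierarchical ensemble classification with majority voting.

Stage 1 assigns every pixel one of eight classes: the three native
formations (grassland, savanna, forest) or one of five other covers.
Stage 2 re-classifies native pixels to the physiognomy level *within* their
assigned formation, training a fresh forest on that formation's
physiognomy samples only. Each stage is an ensemble: the random-forest
fit/predict cycle is repeated over fresh random 80% zone subsets of the
training pool, per-pixel votes are tallied, and a class is accepted only
with a strict majority (> 50% of votes); stage-1 non-majority pixels stay
unclassified, stage-2 non-majority pixels stay at the formation level.
The routine is repeated over several outer splits, each withholding a
different 20% validation set of zones; the presented map is the majority
over all outer x inner runs, and the per-pixel classification probability
is the percentage of runs that voted for the final class.

Seed fan-out: the master seed spawns one stream per outer repeat, which
spawns the split stream and one stream per inner stage, so any single run
is re-creatable in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureCube
from .raster import GridSpec
from .reference import (ReferenceSample, active_samples, draw_training_zones,
                        split_zones)
from .scheme import ClassScheme, DEFAULT_SCHEME

__all__ = ["VoteGrid", "ClassifiedMap", "TwoStageResult", "fit_forest",
           "run_stage", "majority_vote", "two_stage_routine"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VoteGrid:
    """Per-pixel vote counts per candidate class over ensemble runs.

    ``counts`` has shape (n_classes, rows, cols); a pixel's votes sum to at
    most ``total_runs`` (less where a run did not predict the pixel).
    """

    classes: tuple[str, ...]
    counts: np.ndarray
    total_runs: int

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.classes):
            raise ValueError("vote planes do not match class list")
        if (self.counts.sum(axis=0) > self.total_runs).any():
            raise ValueError("vote sum exceeds total runs")


def majority_vote(votes: VoteGrid, totals: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Winning class index per pixel (-1 where no strict majority) and the
    winner's percentage of the votes.

    A class wins only with strictly more than 50% of the per-pixel total;
    an exact 50% share (including two-way ties) yields no winner.
    ``totals`` overrides the per-pixel denominator (defaults to the summed
    votes).
    """
    if votes.total_runs < 1:
        raise ValueError("majority vote needs at least one run")
    counts = votes.counts
    if totals is None:
        totals = counts.sum(axis=0)
    win = counts.argmax(axis=0)
    win_votes = np.take_along_axis(counts, win[None], axis=0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = 100.0 * win_votes / totals
    has_majority = win_votes * 2 > totals
    winner = np.where(has_majority, win, -1)
    prob = np.where(has_majority, prob, np.nan)
    return winner, prob


@dataclass
class ClassifiedMap:
    """Final per-pixel class, stage reached and classification probability.

    ``class_codes`` carries terminal codes for physiognomy-stage pixels,
    formation codes for formation-stage pixels, 0 for unclassified and the
    scheme's nodata code for invalid pixels. ``stage`` is 0/1/2 for
    unclassified/formation/physiognomy (-1 = nodata); ``probability`` is
    the per-pixel percentage of runs agreeing with the final class.
    """

    class_codes: np.ndarray
    stage: np.ndarray
    probability: np.ndarray
    grid: GridSpec
    scheme: ClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    provenance: dict = field(default_factory=dict)

    def class_labels(self) -> np.ndarray:
        """Object array of class code strings ('' = unclassified/nodata)."""
        out = np.full(self.class_codes.shape, "", dtype=object)
        for code, name in self.scheme.class_of.items():
            out[self.class_codes == code] = name
        return out


# ---------------------------------------------------------------------------
# sample bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _Samples:
    """Reference samples resolved onto the cube grid with their features."""

    zone: np.ndarray       # (n,) zone ids
    terminal: np.ndarray   # (n,) terminal class codes (object)
    formation: np.ndarray  # (n,) stage-1 class codes (object)
    flat: np.ndarray       # (n,) flat index into the cube grid
    X: np.ndarray          # (n, n_features)

    def subset(self, keep: np.ndarray) -> "_Samples":
        return _Samples(self.zone[keep], self.terminal[keep],
                        self.formation[keep], self.flat[keep], self.X[keep])

    def zones_by_class(self, labels: np.ndarray) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for z, lab in zip(self.zone, labels):
            lst = out.setdefault(str(lab), [])
            if int(z) not in lst:
                lst.append(int(z))
        return out


def _resolve_samples(cube: FeatureCube, samples: list[ReferenceSample],
                     sample_grid: GridSpec | None,
                     X_all: np.ndarray, valid: np.ndarray) -> _Samples:
    """Map reference pixels (on their native grid) onto cube pixels and
    attach feature vectors; samples on nodata pixels are dropped."""
    samples = active_samples(samples)
    sample_grid = sample_grid or cube.grid
    rows = np.array([s.row for s in samples])
    cols = np.array([s.col for s in samples])
    if sample_grid == cube.grid:
        rr, cc = rows, cols
    else:
        x = sample_grid.origin_x + (cols + 0.5) * sample_grid.pixel_size
        y = sample_grid.origin_y - (rows + 0.5) * sample_grid.pixel_size
        rr, cc = cube.grid.xy_to_rowcol(x, y)
    on_grid = (rr >= 0) & (rr < cube.grid.rows) & \
              (cc >= 0) & (cc < cube.grid.cols)
    flat = rr.clip(0, cube.grid.rows - 1) * cube.grid.cols \
        + cc.clip(0, cube.grid.cols - 1)
    ok = on_grid & valid[flat]
    if not ok.all():
        warnings.warn(f"dropped {int((~ok).sum())} reference pixels with "
                      "nodata features")
    return _Samples(
        zone=np.array([s.zone_id for s in samples])[ok],
        terminal=np.array([s.terminal_class for s in samples],
                          dtype=object)[ok],
        formation=np.array([s.formation_class for s in samples],
                           dtype=object)[ok],
        flat=flat[ok], X=X_all[flat[ok]])


# ---------------------------------------------------------------------------
# forests and stage runs
# ---------------------------------------------------------------------------

def fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int = 100,
               seed: int = 0) -> RandomForestClassifier:
    """Fit one ensemble member: an untuned random forest (default
    hyperparameters apart from the tree count)."""
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if not np.isfinite(X).all():
        raise ValueError("training features contain missing values")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 n_jobs=1)
    clf.fit(X, y)
    return clf


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_stage(X_pixels: np.ndarray, pool: _Samples, labels: np.ndarray,
              candidate_classes: tuple[str, ...], n_runs: int,
              seed_seq: np.random.SeedSequence, n_trees: int = 100,
              train_fraction: float = 0.8, keep_pixel_preds: bool = False):
    """One ensemble stage over one pixel set.

    For each run: draw a fresh ``train_fraction`` zone subset of the pool
    (resampling the draw if a candidate class drops out), fit a forest,
    predict every pixel and tally votes.

    Returns ``(counts, holdout_records, pixel_preds)`` where ``counts`` is
    (n_classes, n_pixels) vote counts, ``holdout_records`` holds per run
    the boolean mask of pool samples left out of training and the forest's
    predictions at all pool samples, and ``pixel_preds`` (only when
    ``keep_pixel_preds``) holds the per-run predicted class of every pixel.
    """
    cls_idx = {c: i for i, c in enumerate(candidate_classes)}
    zones_by_class = pool.zones_by_class(labels)
    missing = [c for c in candidate_classes if c not in zones_by_class]
    if missing:
        raise ValueError(f"training pool lacks zones for {missing}")
    counts = np.zeros((len(candidate_classes), X_pixels.shape[0]),
                      dtype=np.uint32)
    holdout_records, pixel_preds = [], []
    run_seqs = seed_seq.spawn(n_runs)
    for r in range(n_runs):
        rng = np.random.default_rng(run_seqs[r])
        for _attempt in range(20):
            train_zones = draw_training_zones(zones_by_class,
                                              train_fraction, rng)
            in_train = np.isin(pool.zone, list(train_zones))
            if set(labels[in_train].astype(str)) == set(candidate_classes):
                break
            warnings.warn("inner-run subset missed a class; resampled")
        clf = fit_forest(pool.X[in_train], labels[in_train].astype(str),
                         n_trees=n_trees, seed=_seed_int(run_seqs[r]))
        pred = clf.predict(X_pixels)
        for c, i in cls_idx.items():
            counts[i] += (pred == c)
        holdout_records.append((~in_train, clf.predict(pool.X)))
        if keep_pixel_preds:
            pixel_preds.append(pred)
    return counts, holdout_records, pixel_preds


# ---------------------------------------------------------------------------
# the full routine
# ---------------------------------------------------------------------------

@dataclass
class TwoStageResult:
    """Everything the two-stage routine produces."""

    overall: ClassifiedMap
    per_outer_maps: list[ClassifiedMap]
    stage1_votes: VoteGrid
    stage2_votes: VoteGrid
    #: per run (n_outer x n_inner entries): (truth terminal, truth
    #: formation, predicted label) at that outer repeat's validation
    #: samples; the prediction is a physiognomy, a formation (stage-2
    #: fallback), an other-cover class, or '' (unclassified) — the
    #: combined stage-1+2 assessment data
    run_validation: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    #: per run: (truth formation, predicted formation) at the run's
    #: stage-1 holdout (the unused ~20% of the pool)
    run_stage1_holdout: list[tuple[np.ndarray, np.ndarray]]
    provenance: dict = field(default_factory=dict)


def two_stage_routine(cube: FeatureCube, samples: list[ReferenceSample],
                      scheme: ClassScheme = DEFAULT_SCHEME,
                      n_outer: int = 10, n_inner: int = 50,
                      n_trees: int = 100, seed: int = 0,
                      sample_grid: GridSpec | None = None,
                      withhold_fraction: float = 0.2,
                      train_fraction: float = 0.8) -> TwoStageResult:
    """Run the full hierarchical ensemble routine.

    Per outer repeat: withhold a fresh 20% validation set of zones, run the
    stage-1 ensemble (``n_inner`` runs) over all valid pixels, form the
    formation-level majority map, then run the stage-2 ensemble per native
    formation over that formation's pixels. Votes accumulate across all
    outer repeats; the overall map is the majority over all
    ``n_outer * n_inner`` runs.
    """
    X_all, valid = cube.matrix()
    valid_idx = np.nonzero(valid)[0]
    X_pix = X_all[valid_idx]
    shape = cube.grid.shape
    n_pix = valid_idx.size

    res = _resolve_samples(cube, samples, sample_grid, X_all, valid)
    stage1_classes = scheme.stage1_classes
    phys_classes = scheme.physiognomies

    g_stage1 = np.zeros((len(stage1_classes), n_pix), dtype=np.uint32)
    g_stage2 = np.zeros((len(phys_classes), n_pix), dtype=np.uint32)
    per_outer_maps: list[ClassifiedMap] = []
    run_validation: list = []
    run_stage1_holdout: list = []

    master = np.random.SeedSequence(entropy=int(seed))
    for o, outer_ss in enumerate(master.spawn(n_outer)):
        split_ss, s1_ss, s2_ss = outer_ss.spawn(3)
        val_zones, pool_zones = split_zones(
            samples, withhold_fraction, np.random.default_rng(split_ss))
        pool = res.subset(np.isin(res.zone, list(pool_zones)))
        val = res.subset(np.isin(res.zone, list(val_zones)))
        val_pos = _positions_in(valid_idx, val.flat)

        # ---- stage 1 ----------------------------------------------------
        s1_counts, s1_runs, _ = run_stage(
            X_pix, pool, pool.formation, stage1_classes, n_inner, s1_ss,
            n_trees, train_fraction)
        g_stage1 += s1_counts
        for holdout_mask, pool_pred in s1_runs:
            run_stage1_holdout.append(
                (pool.formation[holdout_mask].astype(str),
                 pool_pred[holdout_mask].astype(str)))

        o_winner, _ = _flat_majority(s1_counts)

        # ---- stage 2 per native formation -------------------------------
        o_stage2 = np.zeros((len(phys_classes), n_pix), dtype=np.uint32)
        # per-run combined prediction at validation samples, seeded with
        # the outer stage-1 majority class (or '' if unclassified)
        base = np.full(val.zone.size, "", dtype=object)
        w_at_val = o_winner[val_pos]
        for i, w in enumerate(w_at_val):
            if w >= 0:
                base[i] = stage1_classes[w]
        val_preds = [base.copy() for _ in range(n_inner)]

        form_seqs = s2_ss.spawn(len(scheme.formations))
        for fi, formation in enumerate(scheme.formations):
            form_ss = form_seqs[fi]
            pix_mask = o_winner == stage1_classes.index(formation)
            members = scheme.physiognomies_of(formation)
            fpool = pool.subset(np.isin(pool.terminal.astype(str), members))
            if not pix_mask.any() or fpool.zone.size == 0:
                continue
            counts, _, pixel_preds = run_stage(
                X_pix[pix_mask], fpool, fpool.terminal, members, n_inner,
                form_ss, n_trees, train_fraction, keep_pixel_preds=True)
            for ci, c in enumerate(members):
                o_stage2[phys_classes.index(c), pix_mask] += counts[ci]
            sel = pix_mask[val_pos]
            if sel.any():
                pos_in_subset = np.cumsum(pix_mask)[val_pos[sel]] - 1
                for r in range(n_inner):
                    val_preds[r][sel] = pixel_preds[r][pos_in_subset]

        run_validation.extend(
            (val.terminal.astype(str), val.formation.astype(str),
             val_preds[r].astype(str)) for r in range(n_inner))
        g_stage2 += o_stage2
        per_outer_maps.append(_compose_map(
            o_winner, s1_counts, o_stage2, valid_idx, shape, cube,
            scheme, provenance={"outer": o}))

    stage1_votes = VoteGrid(stage1_classes,
                            _unflatten(g_stage1, valid_idx, shape),
                            n_outer * n_inner)
    stage2_votes = VoteGrid(phys_classes,
                            _unflatten(g_stage2, valid_idx, shape),
                            n_outer * n_inner)
    overall_winner, _ = _flat_majority(g_stage1)
    overall = _compose_map(
        overall_winner, g_stage1, g_stage2, valid_idx, shape, cube, scheme,
        provenance={"feature_space": cube.config.identifier,
                    "seed": int(seed), "n_outer": n_outer,
                    "n_inner": n_inner})
    return TwoStageResult(overall, per_outer_maps, stage1_votes,
                          stage2_votes, run_validation, run_stage1_holdout,
                          provenance=overall.provenance)


def _flat_majority(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict-majority winner over flat (n_classes, n_pixels) vote counts."""
    totals = counts.sum(axis=0)
    win = counts.argmax(axis=0)
    win_votes = np.take_along_axis(counts, win[None], axis=0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = 100.0 * win_votes / totals
    ok = win_votes * 2 > totals
    return np.where(ok, win, -1), np.where(ok, prob, np.nan)


def _positions_in(valid_idx: np.ndarray, flat: np.ndarray) -> np.ndarray:
    """Positions of cube flat indices within the valid-pixel ordering."""
    order = np.searchsorted(valid_idx, flat)
    if order.size and not np.array_equal(valid_idx[order], flat):
        raise ValueError("sample pixel not among valid pixels")
    return order


def _unflatten(planes: np.ndarray, valid_idx: np.ndarray, shape
               ) -> np.ndarray:
    out = np.zeros((planes.shape[0], shape[0] * shape[1]),
                   dtype=planes.dtype)
    out[:, valid_idx] = planes
    return out.reshape((planes.shape[0],) + tuple(shape))


def _compose_map(winner1, s1_counts, s2_counts, valid_idx, shape, cube,
                 scheme, provenance=None) -> ClassifiedMap:
    """Combine stage-1 and stage-2 vote counts into a classified map.

    Stage-2 majorities are evaluated against the per-pixel total of all
    stage-2 predictions and restricted to the physiognomies of the pixel's
    stage-1 formation, so the hierarchy is consistent by construction.
    """
    stage1_classes = scheme.stage1_classes
    phys_classes = scheme.physiognomies
    n_pix = winner1.size
    codes = np.zeros(n_pix, dtype=np.int16)
    stage = np.zeros(n_pix, dtype=np.int8)
    prob = np.full(n_pix, np.nan)

    s1_tot = s1_counts.sum(axis=0)
    s1_win_votes = np.take_along_axis(
        s1_counts, np.clip(winner1, 0, None)[None], axis=0)[0]
    for i, cls in enumerate(stage1_classes):
        m = winner1 == i
        if not m.any():
            continue
        codes[m] = scheme.code_of[cls]
        stage[m] = 1
        prob[m] = 100.0 * s1_win_votes[m] / s1_tot[m]

    s2_tot = s2_counts.sum(axis=0)
    for formation in scheme.formations:
        fmask = (winner1 == stage1_classes.index(formation)) & (s2_tot > 0)
        if not fmask.any():
            continue
        members = scheme.physiognomies_of(formation)
        sub = s2_counts[[phys_classes.index(m) for m in members]][:, fmask]
        tot = s2_tot[fmask]
        win = sub.argmax(axis=0)
        win_votes = np.take_along_axis(sub, win[None], axis=0)[0]
        has_maj = win_votes * 2 > tot
        idx = np.nonzero(fmask)[0][has_maj]
        codes[idx] = np.array([scheme.code_of[members[w]]
                               for w in win[has_maj]], dtype=np.int16)
        stage[idx] = 2
        prob[idx] = 100.0 * win_votes[has_maj] / tot[has_maj]

    full_codes = np.full(shape[0] * shape[1], scheme.nodata_code,
                         dtype=np.int16)
    full_stage = np.full(shape[0] * shape[1], -1, dtype=np.int8)
    full_prob = np.full(shape[0] * shape[1], np.nan)
    full_codes[valid_idx] = codes
    full_stage[valid_idx] = stage
    full_prob[valid_idx] = prob
    return ClassifiedMap(full_codes.reshape(shape),
                         full_stage.reshape(shape),
                         full_prob.reshape(shape), cube.grid, scheme,
                         provenance or {})
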