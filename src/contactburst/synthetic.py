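"""Synthetic mobilization-screen studies.

Generates complete, internally consistent datasets with the statistical
structure the analysis assumes: a binned contact matrix with power-law
distance decay and TAD-boundary attenuation, insertion positions
concentrated inside the TAD, per-line replicate expression means with
multiplicative day-to-day noise, and per-line smFISH count histograms
drawn from the ground-truth bursting model.  Ground truth and the
study seed are always serialized next to the data, so every downstream
estimate can be checked against what generated it.

Default geometry: a 2.6 Mb captured region at 6.4 kb resolution around
a 560 kb TAD, with the promoter 80 kb inside the 5' boundary.  The
default decay exponent and boundary factor are calibrated so that the
viewpoint contact probability falls from ~1 near the promoter to ~0.05
at the distal TAD boundary and drops a further ~3-fold across it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as cbio
from .contact_maps import (BinnedContactMatrix, ViewpointProfile,
                           counts_to_probability, viewpoint_profile)
from .inference import (ApparentModel, FishDataset, FishLine, PhenomModel,
                        ScreenDataset)

__all__ = ["StudyConfig", "StudyBundle", "truth_model",
           "contact_probability", "gen_contact_matrix", "gen_insertions",
           "gen_screen", "gen_fish", "gen_full_study"]

DEFAULT_PHENOM_TRUTH = {
    "kon0": 0.02, "kon1": 2.0, "k_off": 1.5, "mu": 40.0,
    "c": 0.12, "h": 2.8,
}
DEFAULT_APPARENT_TRUTH = {
    "kon_basal": 0.02, "kon_enh": 2.0, "beta": 4.0, "n": 5,
    "k_off": 1.5, "mu": 40.0,
}


@dataclass
class StudyConfig:
    """Ground-truth description of a synthetic screen.

    All coordinates are 0-based bp on a synthetic chromosome.  The
    contact-probability profile seen from the promoter is
    ``(1 + d/decay_scale)**(-decay_exponent)`` attenuated by
    ``1/boundary_factor`` per crossed TAD boundary.
    """

    seed: int
    chrom: str = "chrS"
    region_start: int = 0
    region_end: int = 2_600_000
    bin_size: int = 6400
    tad_start: int = 1_020_000
    tad_end: int = 1_580_000          # 560 kb TAD
    promoter: int = 1_100_000         # 80 kb inside the 5' boundary
    boundary_factor: float = 3.0
    decay_exponent: float = 0.8
    decay_scale: float = 6400.0
    count_scale: float = 2000.0       # Poisson intensity at the reference
    n_lines: int = 135
    inside_fraction: float = 0.99
    n_promoter_only: int = 3
    n_replicates: int = 3
    replicate_cv: float = 0.10
    fish_lines: int = 6
    fish_cells: int = 300
    model: str = "phenomenological"   # or "apparent"
    truth: dict = None

    def __post_init__(self):
        if self.truth is None:
            self.truth = dict(DEFAULT_PHENOM_TRUTH
                              if self.model == "phenomenological"
                              else DEFAULT_APPARENT_TRUTH)
        if self.model not in ("phenomenological", "apparent"):
            raise ValueError(f"unknown ground-truth model {self.model!r}")

    def to_config(self, path) -> None:
        flat = asdict(self)
        truth = flat.pop("truth")
        flat.update({f"truth_{k}": v for k, v in truth.items()})
        cbio.write_config(path, flat)


def truth_model(cfg: StudyConfig):
    if cfg.model == "phenomenological":
        return PhenomModel(**cfg.truth)
    t = dict(cfg.truth)
    t["n"] = int(t["n"])
    return ApparentModel(**t)


def _decay(cfg: StudyConfig, d):
    return np.power(1.0 + np.asarray(d, float) / cfg.decay_scale,
                    -cfg.decay_exponent)


def contact_probability(cfg: StudyConfig, position):
    """Ground-truth promoter contact probability at genomic position(s).

    Shifted power-law decay with a fold drop per crossed TAD boundary,
    normalized to the adjacent-bin reference distance so that the
    contact-map conversion rule (divide by the anchor-adjacent bins)
    recovers these values from the sampled matrix.  With the default
    geometry this puts p_c ~ 0.05 just inside the distal TAD boundary
    and ~3-fold lower outside it.
    """
    pos = np.asarray(position, float)
    d = np.abs(pos - cfg.promoter)
    p = _decay(cfg, d) / _decay(cfg, cfg.bin_size)
    crossings = ((pos < cfg.tad_start).astype(int)
                 + (pos >= cfg.tad_end).astype(int))
    p = p * cfg.boundary_factor ** (-crossings.astype(float))
    out = np.clip(p, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _pair_intensity(cfg: StudyConfig, pos_a, pos_b):
    """Expected contact count between two loci (symmetric in its
    arguments), sharing the decay/boundary shape of the viewpoint."""
    d = np.abs(pos_a - pos_b)
    decay = _decay(cfg, d)
    for b in (cfg.tad_start, cfg.tad_end):
        crossed = (pos_a < b) != (pos_b < b)
        decay = decay * np.where(crossed, 1.0 / cfg.boundary_factor, 1.0)
    return cfg.count_scale * decay


def gen_contact_matrix(cfg: StudyConfig, rng: np.random.Generator):
    """Poisson-sampled symmetric contact matrix plus the promoter
    viewpoint profile converted to probabilities."""
    n = -(-(cfg.region_end - cfg.region_start) // cfg.bin_size)
    centers = (cfg.region_start + cfg.bin_size * np.arange(n)
               + cfg.bin_size / 2)
    lam = _pair_intensity(cfg, centers[:, None], centers[None, :])
    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(lam[iu])
    counts = counts + np.triu(counts, 1).T
    mat = BinnedContactMatrix(cfg.chrom, cfg.region_start, cfg.region_end,
                              cfg.bin_size, counts)
    profile = counts_to_probability(viewpoint_profile(mat, cfg.promoter))
    return mat, profile


def gen_insertions(cfg: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Insertion table: ``inside_fraction`` of lines land uniformly in
    the TAD, the rest uniformly in the remaining captured region."""
    n_inside = int(rng.binomial(cfg.n_lines, cfg.inside_fraction))
    pos_in = rng.integers(cfg.tad_start, cfg.tad_end, size=n_inside)
    n_out = cfg.n_lines - n_inside
    out_pos = []
    while len(out_pos) < n_out:
        cand = int(rng.integers(cfg.region_start, cfg.region_end))
        if not (cfg.tad_start <= cand < cfg.tad_end):
            out_pos.append(cand)
    positions = np.concatenate([pos_in, np.array(out_pos, dtype=int)])
    orientation = rng.choice(["+", "-"], size=cfg.n_lines)
    return pd.DataFrame({
        "line_id": [f"L{i:04d}" for i in range(cfg.n_lines)],
        "position": positions.astype(int),
        "orientation": orientation,
    })


def gen_screen(cfg: StudyConfig, insertions: pd.DataFrame,
               rng: np.random.Generator) -> ScreenDataset:
    """Per-line replicate expression means from the ground-truth model.

    Each line's true mean is the model mean at its contact probability;
    replicates add multiplicative log-normal noise at the configured
    CV.  Promoter-only control lines enter at p_c = 0.
    """
    model = truth_model(cfg)
    p_c = contact_probability(cfg, insertions["position"].to_numpy())
    ids = insertions["line_id"].tolist()
    pos = insertions["position"].to_numpy()
    ori = insertions["orientation"].to_numpy()
    if cfg.n_promoter_only:
        ids = ids + [f"P{i:02d}" for i in range(cfg.n_promoter_only)]
        pos = np.concatenate([pos, np.full(cfg.n_promoter_only,
                                           cfg.promoter)])
        ori = np.concatenate([ori, np.full(cfg.n_promoter_only, "+")])
        p_c = np.concatenate([p_c, np.zeros(cfg.n_promoter_only)])
    true_mean = np.asarray(model.mean(p_c), float)
    sigma = np.sqrt(np.log1p(cfg.replicate_cv ** 2))
    if sigma > 0:
        noise = rng.lognormal(-0.5 * sigma ** 2, sigma,
                              size=(len(ids), cfg.n_replicates))
    else:
        noise = np.ones((len(ids), cfg.n_replicates))
    reps = true_mean[:, None] * noise
    return ScreenDataset(ids, pos, ori, p_c, reps.mean(axis=1),
                         reps.std(axis=1, ddof=1) if cfg.n_replicates > 1
                         else np.zeros(len(ids)),
                         np.full(len(ids), cfg.n_replicates))


def gen_fish(cfg: StudyConfig, screen: ScreenDataset,
             rng: np.random.Generator) -> FishDataset:
    """smFISH histograms for a panel of lines spanning the contact-
    probability range (plus a promoter-only line when present), sampled
    from the ground-truth stationary pmf."""
    if len(screen) == 0 or cfg.fish_lines == 0 or cfg.fish_cells == 0:
        return FishDataset([])
    model = truth_model(cfg)
    targets = np.linspace(0.0, 1.0, cfg.fish_lines)
    chosen = []
    for t in targets:
        idx = int(np.argmin(np.abs(screen.p_c - t)))
        if idx not in chosen:
            chosen.append(idx)
    lines = []
    for idx in chosen:
        p = float(screen.p_c[idx])
        pmf = model.pmf(p)
        counts = rng.choice(pmf.size, size=cfg.fish_cells, p=pmf / pmf.sum())
        hist = np.bincount(counts)
        lines.append(FishLine(screen.line_id[idx], p, hist))
    return FishDataset(lines)


@dataclass
class StudyBundle:
    """Everything one synthetic study produces, plus its ground truth."""

    config: StudyConfig
    matrix: BinnedContactMatrix
    profile: ViewpointProfile
    insertions: pd.DataFrame
    screen: ScreenDataset
    fish: FishDataset
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.config.to_config(os.path.join(outdir, "study_config.txt"))
        self.matrix.to_dense_tsv(os.path.join(outdir, "contact_matrix.tsv"))
        cbio.write_bedgraph(
            os.path.join(outdir, "viewpoint_probability.bedgraph"),
            self.profile.chrom, self.profile.bin_starts,
            self.profile.bin_starts + self.profile.bin_size,
            self.profile.values)
        self.insertions.to_csv(os.path.join(outdir, "insertions.tsv"),
                               sep="\t", index=False)
        self.screen.to_tsv(os.path.join(outdir, "screen.tsv"))
        self.fish.to_cells_csv(os.path.join(outdir, "fish_cells.csv"))
        cbio.write_bed(os.path.join(outdir, "tad.bed"), pd.DataFrame({
            "chrom": [self.config.chrom],
            "start": [self.config.tad_start],
            "end": [self.config.tad_end],
            "name": ["TAD"]}))


def gen_full_study(cfg: StudyConfig, outdir=None) -> StudyBundle:
    """Compose a full study.  All randomness flows from the single study
    seed through named substreams (matrix, insertions, screen, FISH)."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_mat, rng_ins, rng_scr, rng_fish = (
        np.random.default_rng(s) for s in ss.spawn(4))
    matrix, profile = gen_contact_matrix(cfg, rng_mat)
    insertions = gen_insertions(cfg, rng_ins)
    screen = gen_screen(cfg, insertions, rng_scr)
    fish = gen_fish(cfg, screen, rng_fish)
    bundle = StudyBundle(cfg, matrix, profile, insertions, screen, fish,
                         truth=dict(cfg.truth, model=cfg.model,
                                    seed=cfg.seed))
    if outdir is not None:
        bundle.write(outdir)
    return bundle
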