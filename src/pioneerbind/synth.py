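"""Ground-truth synthetic genomes, binding landscapes and tag libraries.

The generator emulates the design of an induced-TF study: several TFs
share homeodomain-like motif preferences (a TAAT-core "anterior" motif,
a TTTAT-core "posterior" motif and a bipartite cofactor+posterior motif)
but differ in their ability to occupy motif instances buried in
chromatin that was inaccessible before induction.  That ability is
parameterized per TF as a pioneer index pi in [0,1] multiplying expected
occupancy at inaccessible sites, and an opener strength adding ATAC-seq
signal at bound sites after induction.

Sites are planted on a jittered grid so that accessible-domain truth
intervals around accessible sites never swallow an inaccessible
neighbour, keeping the accessible/inaccessible truth partition exact.
ChIP-seq replicates draw negative-binomial site counts (mean m,
variance m + phi*m^2) and place each signal tag at the site point plus a
Normal(0, sigma) fragment offset; the remaining depth is uniform
background so that every TF's library has the same expected total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import Genome, TagLibrary, ChromTags, GenomicInterval

# --------------------------------------------------------------------------
# motif models


@dataclass
class MotifModel:
    """Position probability matrix over (A,C,G,T)."""

    name: str
    matrix: np.ndarray  # (width, 4)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("motif matrix must be width x 4")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.name!r}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one sequence from the probability matrix."""
        idx = [rng.choice(4, p=row) for row in self.matrix]
        return "".join("ACGT"[i] for i in idx)


def _ppm(consensus: str, soft: str = "", p_core: float = 0.97,
         p_soft: float = 0.7) -> np.ndarray:
    """Probability matrix with a near-deterministic consensus core;
    positions listed in ``soft`` (comma-separated indices, typically the
    flanks) get a weaker preference, as in curated homeodomain PWMs."""
    m = np.full((len(consensus), 4), (1 - p_core) / 3)
    for i, b in enumerate(consensus):
        m[i, "ACGT".index(b)] = p_core
    for i in soft.split(",") if soft else []:
        i = int(i)
        m[i] = np.full(4, (1 - p_soft) / 3)
        m[i, "ACGT".index(consensus[i])] = p_soft
    return m / m.sum(axis=1, keepdims=True)


def default_motifs() -> dict[str, MotifModel]:
    """Built-in motif models: anterior TAAT core, posterior TTTAT core,
    a HOX13-like TTTAC core and a bipartite cofactor+posterior motif.
    Core positions are near-deterministic (p=0.97), flanks soft (p=0.7)."""
    return {
        "anterior": MotifModel("anterior", _ppm("CTAATG", soft="0,5")),
        "posterior": MotifModel("posterior", _ppm("TTTATGA", soft="5,6")),
        "hox13": MotifModel("hox13", _ppm("TTTACGA", soft="5,6")),
        "bipartite": MotifModel("bipartite", _ppm("TGATTTAT", soft="7")),
    }


# --------------------------------------------------------------------------
# configuration


@dataclass
class TFSpec:
    """A TF's motif affinities and chromatin-engagement parameters.

    pioneer_index multiplies expected occupancy at inaccessible sites;
    opener_strength is the expected number of extra ATAC tags gained per
    replicate at a bound site per unit occupancy after induction.
    """

    name: str
    affinity: dict[str, float]
    pioneer_index: float = 1.0
    opener_strength: float = 0.0

    def __post_init__(self):
        if not any(v > 0 for v in self.affinity.values()):
            raise ValueError(f"TF {self.name!r} needs at least one positive affinity")
        if not 0.0 <= self.pioneer_index <= 1.0:
            raise ValueError("pioneer_index must be in [0, 1]")
        if self.opener_strength < 0:
            raise ValueError("opener_strength must be >= 0")


@dataclass
class CategoryConfig:
    """One planted binding category: motif identity, size, accessibility
    and optional per-TF occupancy multipliers (e.g. a missing cofactor)."""

    label: str
    motif: str
    n_sites: int
    accessible_fraction: float
    tf_multiplier: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.accessible_fraction <= 1.0:
            raise ValueError("accessible_fraction must be in [0, 1]")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")


@dataclass
class LandscapeConfig:
    """Desk-scale scenario parameters (a 10 Mb genome over 4 chromosomes)."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 2_500_000 for i in range(1, 5)})
    base_composition: tuple = (0.29, 0.21, 0.21, 0.29)
    categories: list[CategoryConfig] = field(default_factory=list)
    site_spacing: int = 2_000          # grid pitch for planted sites
    site_jitter: int = 300             # uniform jitter around grid points
    domain_halfwidth: tuple = (450, 700)
    n_extra_domains: int = 150         # accessible domains without sites
    chip_depth: int = 400_000          # tags per ChIP replicate
    atac_depth: int = 2_000_000        # tags per ATAC replicate
    n_replicates: int = 2
    dispersion: float = 0.05           # NB phi: var = m + phi m^2
    sigma: float = 35.0                # ChIP fragment offset spread (bp)
    depth_scale: float = 100.0         # expected tags/replicate at occupancy 1
    atac_rate_ratio: float = 10.0      # domain:background per-bp rate ratio
    opener_sigma: float = 150.0        # spread of post-induction ATAC gain (bp)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def default_tf_specs() -> list[TFSpec]:
    """Three TFs: A binds the anterior motif, B and C the posterior motif;
    B is a strong pioneer (pi=0.9), C a weak one (pi=0.1)."""
    return [
        TFSpec("A", {"anterior": 1.0, "bipartite": 1.0, "posterior": 0.05},
               pioneer_index=0.5, opener_strength=30.0),
        TFSpec("B", {"posterior": 1.0, "bipartite": 1.0, "anterior": 0.05},
               pioneer_index=0.9, opener_strength=80.0),
        TFSpec("C", {"posterior": 1.0, "bipartite": 1.0, "anterior": 0.05},
               pioneer_index=0.1, opener_strength=30.0),
    ]


def default_categories(n_sites: int = 800) -> list[CategoryConfig]:
    """Five binding categories plus unbound controls.

    The B-specific category is planted fully inaccessible: only the
    strong pioneer B can occupy it.  The A,B>C category models a
    C-missing cofactor via an occupancy multiplier.
    """
    return [
        CategoryConfig("A=B=C", "bipartite", n_sites, 1.0),
        CategoryConfig("A>B,C", "anterior", n_sites, 1.0),
        CategoryConfig("B>A,C", "posterior", n_sites, 0.0),
        CategoryConfig("A,B>C", "bipartite", n_sites, 1.0, {"C": 0.05}),
        CategoryConfig("B,C>A", "posterior", n_sites, 1.0),
        CategoryConfig("control", "none", n_sites, 0.0),
    ]


def default_config(n_sites: int = 800) -> LandscapeConfig:
    cfg = LandscapeConfig()
    cfg.categories = default_categories(n_sites)
    return cfg


# --------------------------------------------------------------------------
# truth container


@dataclass
class SyntheticTruth:
    """Planted sites, truth accessible domains and per-TF occupancy."""

    sites: pd.DataFrame      # chrom, point, start, end, motif, accessible, category, lam_<TF>...
    domains: pd.DataFrame    # chrom, start, end, has_site
    config: LandscapeConfig
    tf_names: list[str]
    genes: pd.DataFrame | None = None

    def lam(self, tf: str) -> np.ndarray:
        return self.sites[f"lam_{tf}"].to_numpy()

    def occupancy_table(self) -> pd.DataFrame:
        cols = ["category", "accessible"] + [f"lam_{t}" for t in self.tf_names]
        return (self.sites[cols]
                .groupby(["category", "accessible"], observed=True)
                .mean().reset_index())


# --------------------------------------------------------------------------
# operations


def generate_genome(config: LandscapeConfig, seed: int) -> Genome:
    """I.i.d. background genome from the configured base composition."""
    comp = np.asarray(config.base_composition, dtype=float)
    if comp.shape != (4,) or np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
        raise ValueError("base_composition must be 4 non-negative probs summing to 1")
    for length in config.chrom_lengths.values():
        if length < 10_000:
            raise ValueError("chromosomes must be >= 10 kb")
    rng = np.random.default_rng(seed)
    seqs = {}
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, length in config.chrom_lengths.items():
        idx = rng.choice(4, size=length, p=comp)
        seqs[chrom] = alphabet[idx].tobytes().decode()
    return Genome(seqs)


def _site_slots(config: LandscapeConfig, rng: np.random.Generator):
    """Jittered grid positions with a guaranteed minimum spacing."""
    slots = []
    margin = 2_000
    for chrom, length in config.chrom_lengths.items():
        grid = np.arange(margin, length - margin, config.site_spacing)
        jitter = rng.integers(-config.site_jitter, config.site_jitter + 1,
                              size=len(grid))
        for p in (grid + jitter):
            slots.append((chrom, int(p)))
    return slots


def plant_landscape(genome: Genome, config: LandscapeConfig,
                    tf_specs: list[TFSpec], seed: int,
                    motifs: dict[str, MotifModel] | None = None
                    ) -> tuple[Genome, SyntheticTruth]:
    """Embed motif instances at planted sites and build the truth tables.

    Accessible sites get a truth accessible domain around them;
    inaccessible sites lie outside every domain (guaranteed by the grid
    spacing).  Expected occupancy per TF is
    ``affinity[motif] * category multiplier * (1 if accessible else pi)``.
    """
    motifs = motifs or default_motifs()
    rng = np.random.default_rng(seed)
    n_total = sum(c.n_sites for c in config.categories)
    slots = _site_slots(config, rng)
    n_extra = config.n_extra_domains
    if n_total + n_extra > len(slots):
        raise ValueError(
            f"cannot place {n_total} sites + {n_extra} extra domains in "
            f"{len(slots)} available slots; enlarge the genome")
    order = rng.permutation(len(slots))
    chosen = [slots[i] for i in order[:n_total]]
    extra_slots = [slots[i] for i in order[n_total: n_total + n_extra]]

    seq_bytes = {c: bytearray(genome.sequence(c).encode()) for c in genome.chrom_names}

    rows = []
    cursor = 0
    for cat in config.categories:
        n_acc = int(round(cat.accessible_fraction * cat.n_sites))
        for j in range(cat.n_sites):
            chrom, point = chosen[cursor]
            cursor += 1
            accessible = j < n_acc
            if cat.motif != "none":
                # plant the consensus (strand-randomized) so every planted
                # site scores above any calibrated detection threshold
                model = motifs[cat.motif]
                inst = model.consensus
                if rng.random() < 0.5:
                    inst = _revcomp(inst)
                start = point - model.width // 2
                seq_bytes[chrom][start: start + model.width] = inst.encode()
                mstart, mend = start, start + model.width
            else:
                mstart, mend = point, point + 1
            row = {"chrom": chrom, "point": point, "start": mstart, "end": mend,
                   "motif": cat.motif, "accessible": accessible,
                   "category": cat.label}
            for tf in tf_specs:
                aff = tf.affinity.get(cat.motif, 0.0)
                mult = cat.tf_multiplier.get(tf.name, 1.0)
                lam = aff * mult * (1.0 if accessible else tf.pioneer_index)
                row[f"lam_{tf.name}"] = lam
            rows.append(row)

    sites = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["chrom", "point", "start", "end", "motif", "accessible",
                 "category"] + [f"lam_{t.name}" for t in tf_specs])

    # truth accessible domains around accessible sites + extra empty domains
    dom_rows = []
    lo, hi = config.domain_halfwidth
    for _, s in sites[sites.accessible].iterrows():
        left = int(rng.integers(lo, hi + 1))
        right = int(rng.integers(lo, hi + 1))
        dom_rows.append({"chrom": s.chrom,
                         "start": max(0, s.point - left),
                         "end": min(genome.lengths[s.chrom], s.point + right),
                         "has_site": True})
    for chrom, point in extra_slots:
        half = int(rng.integers(lo, hi + 1))
        dom_rows.append({"chrom": chrom, "start": max(0, point - half),
                         "end": min(genome.lengths[chrom], point + half),
                         "has_site": False})
    domains = (pd.DataFrame(dom_rows) if dom_rows else
               pd.DataFrame(columns=["chrom", "start", "end", "has_site"]))
    if len(domains):
        domains = domains.sort_values(["chrom", "start"]).reset_index(drop=True)

    if len(sites):
        sites = sites.sort_values(["chrom", "point"]).reset_index(drop=True)
        genome2 = Genome({c: seq_bytes[c].decode() for c in genome.chrom_names})
    else:
        genome2 = genome
    truth = SyntheticTruth(sites, domains, config, [t.name for t in tf_specs])
    return genome2, truth


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _uniform_tags(rng, config: LandscapeConfig, n: int):
    """n tags uniform over the genome; returns (chroms, positions, strands)."""
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    which = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[which]).astype(np.int64)
    strands = rng.random(n) < 0.5
    return np.array(chroms, dtype=object)[which], pos, strands


def _assemble_library(config, chroms, positions, strands, **meta) -> TagLibrary:
    lib = TagLibrary(**meta)
    for chrom in config.chrom_lengths:
        mask = chroms == chrom
        pos = positions[mask]
        order = np.argsort(pos, kind="stable")
        lib.tags[chrom] = ChromTags(pos[order], strands[mask][order])
    return lib


def _nb_counts(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws with var = m + phi m^2 via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=mean * phi)
    return rng.poisson(lam)


def simulate_chip(truth: SyntheticTruth, tf_spec: TFSpec,
                  depth: int | None = None, n_replicates: int | None = None,
                  dispersion: float | None = None, sigma: float | None = None,
                  seed: int = 0) -> list[TagLibrary]:
    """ChIP-seq replicate libraries for one TF.

    Per site, replicate counts are NB(depth_scale * lambda, phi); each
    signal tag lands at the site point plus a rounded Normal(0, sigma)
    offset with a random strand.  Background tags fill the library up to
    ``depth`` uniformly, so expected totals match across TFs.
    """
    cfg = truth.config
    depth = cfg.chip_depth if depth is None else depth
    n_replicates = cfg.n_replicates if n_replicates is None else n_replicates
    phi = cfg.dispersion if dispersion is None else dispersion
    sigma = cfg.sigma if sigma is None else sigma
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    lam = truth.lam(tf_spec.name) if len(truth.sites) else np.empty(0)
    mean = cfg.depth_scale * lam
    site_chrom = truth.sites["chrom"].to_numpy() if len(truth.sites) else np.empty(0, object)
    site_point = truth.sites["point"].to_numpy() if len(truth.sites) else np.empty(0, np.int64)
    chrom_len = cfg.chrom_lengths

    libs = []
    for rep in range(n_replicates):
        counts = _nb_counts(rng, mean, phi) if len(mean) else np.empty(0, np.int64)
        n_signal = int(counts.sum())
        sig_chroms = np.repeat(site_chrom, counts)
        centers = np.repeat(site_point, counts)
        offsets = np.rint(rng.normal(0.0, sigma, size=n_signal)).astype(np.int64)
        sig_pos = centers + offsets
        maxima = np.array([chrom_len[c] - 1 for c in sig_chroms], dtype=np.int64) \
            if n_signal else np.empty(0, np.int64)
        sig_pos = np.clip(sig_pos, 0, maxima if n_signal else None)
        sig_strands = rng.random(n_signal) < 0.5

        n_bg = max(depth - int(round(mean.sum())), 0)
        bg_chroms, bg_pos, bg_strands = _uniform_tags(rng, cfg, n_bg)
        libs.append(_assemble_library(
            cfg,
            np.concatenate([sig_chroms, bg_chroms]),
            np.concatenate([sig_pos, bg_pos]),
            np.concatenate([sig_strands, bg_strands]),
            experiment_id=f"{tf_spec.name}_chip", condition=tf_spec.name,
            replicate_id=f"rep{rep + 1}"))
    return libs


def simulate_input(truth: SyntheticTruth, depth: int | None = None,
                   n_replicates: int = 1, seed: int = 0) -> list[TagLibrary]:
    """Uniform-background input-control libraries."""
    cfg = truth.config
    depth = cfg.chip_depth if depth is None else depth
    rng = np.random.default_rng(seed)
    libs = []
    for rep in range(n_replicates):
        chroms, pos, strands = _uniform_tags(rng, cfg, depth)
        libs.append(_assemble_library(cfg, chroms, pos, strands,
                                      experiment_id="input", condition="input",
                                      replicate_id=f"rep{rep + 1}"))
    return libs


def _complement_intervals(domains: pd.DataFrame, config: LandscapeConfig):
    """Per-chrom complement of the (merged) domain set."""
    comp = {}
    for chrom, length in config.chrom_lengths.items():
        sub = domains[domains.chrom == chrom].sort_values("start")
        gaps, prev = [], 0
        for _, d in sub.iterrows():
            s, e = int(d.start), int(d.end)
            if s > prev:
                gaps.append((prev, s))
            prev = max(prev, e)
        if prev < length:
            gaps.append((prev, length))
        comp[chrom] = gaps
    return comp


def _sample_in_intervals(rng, intervals_by_chrom, n: int):
    """n positions uniform over a set of intervals (weights by length)."""
    flat = [(c, s, e) for c, ivs in intervals_by_chrom.items() for s, e in ivs]
    lens = np.array([e - s for _, s, e in flat], dtype=float)
    which = rng.choice(len(flat), size=n, p=lens / lens.sum())
    offs = (rng.random(n) * lens[which]).astype(np.int64)
    chroms = np.array([flat[i][0] for i in which], dtype=object)
    pos = np.array([flat[i][1] for i in which], dtype=np.int64) + offs
    return chroms, pos


def simulate_atac(truth: SyntheticTruth, bound_tf_specs: list[TFSpec] | None = None,
                  depth: int | None = None, n_replicates: int | None = None,
                  mode: str = "prior", seed: int = 0) -> list[TagLibrary]:
    """ATAC-seq replicate libraries sampled at a fixed sequencing depth.

    The per-bp tag rate is ``atac_rate_ratio`` times higher inside truth
    domains than outside.  In ``post`` mode each site bound by a
    supplied (induced) TF additionally contributes a point-source gain
    component with relative mass ``opener_strength * occupancy`` (in
    prior-depth tag units), spread Normal(0, opener_sigma) around the
    site point.  Exactly ``depth`` tags are drawn from the composite
    rate field, so library totals match across conditions, as they do
    for libraries sequenced to a set depth: accessibility gains
    redistribute density rather than inflating totals.
    """
    if mode not in ("prior", "post"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = truth.config
    depth = cfg.atac_depth if depth is None else depth
    n_replicates = cfg.n_replicates if n_replicates is None else n_replicates
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    domains = truth.domains
    dom_bp = int((domains.end - domains.start).sum()) if len(domains) else 0
    bg_bp = cfg.total_length - dom_bp
    ratio = cfg.atac_rate_ratio
    base_mass = ratio * dom_bp + bg_bp
    dom_intervals = {c: [(int(r.start), int(r.end))
                         for _, r in domains[domains.chrom == c].iterrows()]
                     for c in cfg.chrom_lengths} if dom_bp else {}
    bg_intervals = _complement_intervals(domains, cfg)
    chrom_len = cfg.chrom_lengths

    # point-source gain masses, in the same units as the base rate field
    # (opener_strength is expected extra tags per replicate at prior depth)
    gain_mass = np.zeros(len(truth.sites))
    if mode == "post" and bound_tf_specs and len(truth.sites) and depth > 0:
        for tf in bound_tf_specs:
            if tf.opener_strength > 0:
                gain_mass = gain_mass + tf.opener_strength * truth.lam(tf.name)
        gain_mass = gain_mass * (base_mass / depth)
    total_gain = float(gain_mass.sum())

    libs = []
    for rep in range(n_replicates):
        if depth == 0:
            lib = TagLibrary(experiment_id="atac", condition=mode,
                             replicate_id=f"rep{rep + 1}")
            for c in cfg.chrom_lengths:
                lib.tags[c] = ChromTags(np.empty(0, np.int64), np.empty(0, bool))
            libs.append(lib)
            continue
        mass = np.array([ratio * dom_bp, float(bg_bp), total_gain])
        n_dom, n_bg, n_gain = rng.multinomial(depth, mass / mass.sum()) \
            if total_gain > 0 else (*_split2(rng, depth, mass[:2]), 0)
        parts_c, parts_p = [], []
        if n_dom:
            c1, p1 = _sample_in_intervals(rng, dom_intervals, n_dom)
            parts_c.append(c1)
            parts_p.append(p1)
        if n_bg:
            c2, p2 = _sample_in_intervals(rng, bg_intervals, n_bg)
            parts_c.append(c2)
            parts_p.append(p2)
        if n_gain:
            per_site = rng.multinomial(n_gain, gain_mass / total_gain)
            centers = np.repeat(truth.sites["point"].to_numpy(), per_site)
            chroms = np.repeat(truth.sites["chrom"].to_numpy(), per_site)
            pos = centers + np.rint(
                rng.normal(0, cfg.opener_sigma, n_gain)).astype(np.int64)
            maxima = np.array([chrom_len[c] - 1 for c in chroms])
            parts_c.append(chroms)
            parts_p.append(np.clip(pos, 0, maxima))
        chroms = np.concatenate(parts_c)
        pos = np.concatenate(parts_p)
        strands = rng.random(len(pos)) < 0.5
        libs.append(_assemble_library(cfg, chroms, pos, strands,
                                      experiment_id="atac", condition=mode,
                                      replicate_id=f"rep{rep + 1}"))
    return libs


def _split2(rng, depth: int, mass: np.ndarray):
    """Two-way split of depth (same rng pathing whether or not a zero-mass
    gain component is present)."""
    n_dom = rng.binomial(depth, mass[0] / mass.sum()) if mass[0] > 0 else 0
    return n_dom, depth - n_dom


# --------------------------------------------------------------------------
# expression


#: which TFs drive up-regulation near each planted category
def _up_tfs(category: str, tf_names: list[str]) -> list[str]:
    if category == "control" or ">" not in category and "=" not in category:
        return []
    if "=" in category and ">" not in category:
        return tf_names[:]  # shared
    left = category.split(">")[0]
    return [t.strip() for t in left.split(",")]


def simulate_expression(truth: SyntheticTruth, tf_names: list[str] | None = None,
                        n_genes: int = 2_000, effect_lfc: float = 4.0,
                        genes_per_category: int = 120, seed: int = 0,
                        noise_sd: float = 0.3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene models plus a differential-expression summary table.

    Genes planted next to category sites are up-regulated (LFC =
    effect_lfc + noise, tiny adjusted p) in the contrasts of the TFs that
    bind that category; null genes sit between sites with LFC ~
    Normal(0, 0.2) and uniform adjusted p.  Contrast labels follow
    ``<TF>_vs_base`` and ``<X>_vs_<Y>``.

    Returns (gene_models, expression_records) and stores gene_models on
    ``truth.genes``.
    """
    if effect_lfc <= 0:
        raise ValueError("effect_lfc must be > 0")
    tf_names = tf_names or truth.tf_names
    rng = np.random.default_rng(seed)
    cfg = truth.config
    sites = truth.sites

    gene_rows = []
    gid = 0
    for cat in sites["category"].unique():
        if cat == "control":
            continue
        sub = sites[sites.category == cat]
        take = min(genes_per_category, len(sub))
        pick = sub.iloc[rng.choice(len(sub), size=take, replace=False)]
        for _, s in pick.iterrows():
            tss = int(s.point + rng.integers(-150, 151))
            gene_rows.append({
                "gene": f"g{gid:05d}", "chrom": s.chrom, "strand": "+",
                "tss": tss,
                "length": int(rng.integers(2_000, 20_000)),
                "truth_set": cat, "site_point": int(s.point)})
            gid += 1
    n_null = max(n_genes - len(gene_rows), 0)
    # null genes at slot midpoints, far from any planted site
    mids = []
    for chrom, length in cfg.chrom_lengths.items():
        grid = np.arange(3_000, length - 3_000, cfg.site_spacing)
        mids.extend((chrom, int(g + cfg.site_spacing // 2)) for g in grid)
    order = rng.permutation(len(mids))
    for i in order[:n_null]:
        chrom, tss = mids[i]
        gene_rows.append({"gene": f"g{gid:05d}", "chrom": chrom, "strand": "+",
                          "tss": tss, "length": int(rng.integers(2_000, 20_000)),
                          "truth_set": "null", "site_point": -1})
        gid += 1
    genes = pd.DataFrame(gene_rows).sort_values(["chrom", "tss"]).reset_index(drop=True)

    contrasts = [f"{t}_vs_base" for t in tf_names]
    contrasts += [f"{a}_vs_{b}" for i, a in enumerate(tf_names)
                  for b in tf_names[i + 1:]]
    rec_rows = []
    for _, g in genes.iterrows():
        up = _up_tfs(g.truth_set, tf_names) if g.truth_set != "null" else []
        for con in contrasts:
            if "_vs_base" in con:
                tf = con.split("_vs_")[0]
                true_lfc = effect_lfc if tf in up else 0.0
            else:
                a, b = con.split("_vs_")
                true_lfc = effect_lfc * ((a in up) - (b in up))
            if true_lfc != 0.0:
                lfc = true_lfc + rng.normal(0, noise_sd)
                padj = 10.0 ** (-rng.uniform(4, 8))
            else:
                lfc = rng.normal(0, 0.2)
                padj = rng.uniform()
            rec_rows.append({"gene": g.gene, "contrast": con,
                             "lfc": lfc, "padj": padj})
    records = pd.DataFrame(rec_rows)
    truth.genes = genes
    return genes, records


#: mapping from planted binding category to the matching gene-set label
def matching_gene_set(category: str, direction: str = "up") -> str:
    if "=" in category and ">" not in category:
        return f"shared-{direction}"
    left = category.split(">")[0]
    tfs = [t.strip() for t in left.split(",")]
    return f"{'+'.join(tfs)}-{direction}"
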