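"""Synthetic study generator: parental ribotype pools, dosage-weighted
hybrid copy mixtures, clone libraries with PCR/cloning artifacts and
pseudogenized copies, direct-sequencing consensus records, a matching
secondary-structure template, and leaf landmark datasets.

The defaults reproduce the study conditions of the analysis this package
mechanizes: ITS1/5.8S/ITS2 lengths 241/164/212, between-parent divergence
0.02, a 2:1 maternal:paternal copy dosage in the (triploid) hybrid,
20-clone libraries, and leaf samples of 28/26/41 per group with isotropic
landmark noise. The 5.8S and the conserved motifs are held invariant
between parents (they are conserved at this taxonomic depth); pseudogenized
copies violate exactly that. All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import alphabet
from .polymorphism import call_consensus
from .structure_qc import DEFAULT_MOTIFS
from .types import (
    AlignedSet,
    LandmarkConfiguration,
    RegionAnnotation,
    Role,
    SequenceRecord,
    StructureTemplate,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    L_its1: int = 241
    L_58S: int = 164
    L_its2: int = 212
    n_copies_per_genome: int = 10
    n_parental_variants: int = 3  # copies per pool carrying intragenomic variants
    divergence: float = 0.02  # per-site substitution prob between parent taxa
    intragenomic_poly_rate: float = 0.004
    kappa: float = 2.0  # transition/transversion bias of the mutation process
    dosage: tuple[int, int] = (2, 1)  # maternal : paternal copy dosage
    n_clones: int = 20
    clone_error_rate: float = 2e-5  # per-base PCR/cloning error (proofreading polymerase)
    methylation_bias: float = 0.7  # fraction of errors that are C->T / G->A
    pseudogene_rate: float = 0.2  # fraction of clones drawn as pseudogenized copies
    pseudogene_58s_subs: int = 2  # 5.8S substitutions per pseudogenized copy
    gc_shift_subs: int = 6  # extra G/C -> A/T substitutions in the spacers
    n_chimeras: int = 0
    gc_target: float = 0.58
    # landmarks
    landmark_groups: dict[str, int] = field(
        default_factory=lambda: {"notabilis": 28, "hybrid": 26, "variabilis": 41}
    )
    landmark_sigma: float = 0.02

    def __post_init__(self) -> None:
        for name in ("divergence", "intragenomic_poly_rate", "clone_error_rate",
                     "pseudogene_rate", "methylation_bias"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.L_its1, self.L_58S, self.L_its2) <= 0:
            raise ValueError("region lengths must be positive")
        if min(self.dosage) < 0 or max(self.dosage) == 0:
            raise ValueError("dosage components must be >= 0 and not both 0")

    @property
    def L(self) -> int:
        return self.L_its1 + self.L_58S + self.L_its2

    def regions(self) -> RegionAnnotation:
        return RegionAnnotation(
            {
                "ITS1": (1, self.L_its1),
                "5.8S": (self.L_its1 + 1, self.L_its1 + self.L_58S),
                "ITS2": (self.L_its1 + self.L_58S + 1, self.L),
            }
        )


def paper_like(seed: int = 0, **overrides) -> SimConfig:
    """The 'paper-like' preset: the defaults, with chimera planting enabled
    so the QC scan has a positive control."""
    kw = dict(seed=seed, n_chimeras=1)
    kw.update(overrides)
    return SimConfig(**kw)


@dataclass
class SimTruth:
    """Ground truth referring only to generated records."""

    parent_diff_columns: tuple[int, ...] = ()
    intragenomic_columns: dict[str, tuple[int, ...]] = field(default_factory=dict)
    pseudogene_clones: dict[str, tuple[str, ...]] = field(default_factory=dict)
    chimera_clones: dict[str, dict[str, int]] = field(default_factory=dict)
    mean_shapes: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, tuple):
                return list(x)
            return x

        return json.dumps(
            {
                "parent_diff_columns": list(self.parent_diff_columns),
                "intragenomic_columns": {k: list(v) for k, v in self.intragenomic_columns.items()},
                "pseudogene_clones": {k: list(v) for k, v in self.pseudogene_clones.items()},
                "chimera_clones": self.chimera_clones,
                "mean_shapes": {k: conv(v) for k, v in self.mean_shapes.items()},
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# sequence helpers


def _motif_blocks(cfg: SimConfig) -> list[tuple[int, str]]:
    """(1-based start, resolved motif) blocks embedded in the ancestor and
    protected from mutation: the ITS1 angiosperm motif and the 5.8S blocks
    M1 (at the 5.8S start), M2 (mid), M3 (at the 5.8S end)."""
    its1 = DEFAULT_MOTIFS["ITS1_angiosperm"]
    its1_seq = (its1["head"] + "GATYG" + its1["tail"]).replace("R", "G").replace("Y", "C")
    m1 = DEFAULT_MOTIFS["M1"]["pattern"].replace("Y", "C")
    m2 = DEFAULT_MOTIFS["M2"]["pattern"]
    m3 = DEFAULT_MOTIFS["M3"]["pattern"].replace("Y", "C")
    s58_start = cfg.L_its1 + 1
    s58_end = cfg.L_its1 + cfg.L_58S
    blocks = [
        (40, its1_seq),  # inside ITS1
        (s58_start, m1),
        (s58_start + cfg.L_58S // 2, m2),
        (s58_end - len(m3) + 1, m3),
    ]
    return blocks


def _protected_columns(cfg: SimConfig) -> set[int]:
    out: set[int] = set()
    for start, seq in _motif_blocks(cfg):
        out.update(range(start, start + len(seq)))
    return out


def _random_ancestor(cfg: SimConfig, rng: np.random.Generator) -> str:
    p_gc = cfg.gc_target / 2.0
    p_at = (1.0 - cfg.gc_target) / 2.0
    seq = rng.choice(_BASES, size=cfg.L, p=[p_at, p_gc, p_gc, p_at])
    seq = list("".join(seq))
    for start, block in _motif_blocks(cfg):
        seq[start - 1 : start - 1 + len(block)] = list(block)
    return "".join(seq)


def _mutate(seq: str, columns, rng: np.random.Generator, kappa: float) -> str:
    """Substitute at the given 0-based columns with transition bias kappa."""
    out = list(seq)
    for c in columns:
        base = out[c]
        if base not in "ACGT":
            continue
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
        transversions = [b for b in "ACGT" if b != base and b != transition]
        w = np.array([kappa, 1.0, 1.0])
        w = w / w.sum()
        out[c] = str(rng.choice([transition] + transversions, p=w))
    return "".join(out)


def _mutable_columns(cfg: SimConfig, include_58s: bool) -> np.ndarray:
    protected = _protected_columns(cfg)
    s58_start, s58_end = cfg.L_its1 + 1, cfg.L_its1 + cfg.L_58S
    cols = [
        c
        for c in range(1, cfg.L + 1)
        if c not in protected and (include_58s or not s58_start <= c <= s58_end)
    ]
    return np.array(cols)


# ---------------------------------------------------------------------------
# generators


def gen_parents(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Two parental copy pools diverged from a common ancestor.

    Divergence hits only the spacers (the 5.8S and the conserved motifs stay
    invariant between the parents, as they do between closely related
    species); each pool carries a few intragenomic variant copies.
    Returns (maternal_pool, paternal_pool, truth).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    ancestor = _random_ancestor(cfg, rng)
    mutable = _mutable_columns(cfg, include_58s=False)
    # divergence is the target whole-alignment p-distance between parents:
    # draw the substitution count over all L sites, place it on mutable ones
    n_div = min(rng.binomial(cfg.L, cfg.divergence), len(mutable))
    div_cols = rng.choice(mutable, size=n_div, replace=False)
    # split the divergent columns between the two lineages
    pick = rng.random(n_div) < 0.5
    maternal_cons = _mutate(ancestor, div_cols[pick] - 1, rng, cfg.kappa)
    paternal_cons = _mutate(ancestor, div_cols[~pick] - 1, rng, cfg.kappa)

    truth = SimTruth()
    diff = tuple(
        int(c) for c in range(1, cfg.L + 1) if maternal_cons[c - 1] != paternal_cons[c - 1]
    )
    truth.parent_diff_columns = diff

    pools = {}
    for label, cons, role in (
        ("maternal", maternal_cons, Role.MATERNAL),
        ("paternal", paternal_cons, Role.PATERNAL),
    ):
        records = []
        intragenomic: set[int] = set()
        for k in range(cfg.n_copies_per_genome):
            seq = cons
            if k < cfg.n_parental_variants:
                n_var = rng.binomial(len(mutable), cfg.intragenomic_poly_rate)
                if n_var:
                    var_cols = rng.choice(mutable, size=n_var, replace=False)
                    seq = _mutate(seq, var_cols - 1, rng, cfg.kappa)
                    intragenomic.update(int(c) for c in var_cols)
            records.append(SequenceRecord(f"{label}_copy{k + 1:02d}", seq, label, role))
        pools[label] = records
        truth.intragenomic_columns[label] = tuple(sorted(intragenomic))
    return pools["maternal"], pools["paternal"], truth


def gen_hybrid(maternal_pool, paternal_pool, cfg: SimConfig):
    """Hybrid copy pool mixing parental copies at the dosage ratio.

    With dosage (2, 1) the pool holds two maternal copies for every paternal
    one, so every parent-differentiating column is additive in the pool by
    construction (the additive columns are the parents' truth
    ``parent_diff_columns``).
    """
    dm, dp = cfg.dosage
    pool = []
    k = 1
    for _ in range(dm):
        for rec in maternal_pool:
            pool.append(SequenceRecord(f"hybrid_copy{k:02d}", rec.seq, "hybrid", Role.HYBRID))
            k += 1
    for _ in range(dp):
        for rec in paternal_pool:
            pool.append(SequenceRecord(f"hybrid_copy{k:02d}", rec.seq, "hybrid", Role.HYBRID))
            k += 1
    if not pool:
        raise ValueError("dosage (0, 0): hybrid pool would be empty")
    return pool


def gen_clone_library(
    pool,
    cfg: SimConfig,
    rng: np.random.Generator,
    library_id: str = "lib",
    parents: tuple[SequenceRecord, SequenceRecord] | None = None,
):
    """Sample a clone library from a copy pool with PCR/cloning noise.

    Per-base errors at ``clone_error_rate`` with a C->T / G->A bias;
    a ``pseudogene_rate`` fraction of clones become pseudogenized copies
    (5.8S substitutions plus GC-lowering spacer substitutions); optionally
    ``n_chimeras`` clones are spliced from the two parental consensus
    sequences at a random internal breakpoint. Returns (clones, truth).
    """
    if not pool:
        raise ValueError("empty copy pool")
    truth = SimTruth()
    L = len(pool[0])
    s58_start, s58_end = cfg.L_its1 + 1, cfg.L_its1 + cfg.L_58S
    mutable_all = _mutable_columns(cfg, include_58s=True)
    s58_mutable = np.array([c for c in mutable_all if s58_start <= c <= s58_end])
    clones = []
    pseudo_ids = []
    chimera_info: dict[str, int] = {}

    is_pseudo = rng.random(cfg.n_clones) < cfg.pseudogene_rate
    chimera_slots: set[int] = set()
    if cfg.n_chimeras and parents is not None:
        chimera_slots = set(
            int(i) for i in rng.choice(cfg.n_clones, size=min(cfg.n_chimeras, cfg.n_clones), replace=False)
        )

    for i in range(cfg.n_clones):
        cid = f"{library_id}{i + 1:02d}"
        if i in chimera_slots:
            bp = int(rng.integers(L // 4, 3 * L // 4))  # 0-based split point
            pa, pb = parents
            seq = pa.seq[:bp] + pb.seq[bp:]
            chimera_info[cid] = bp + 1  # last column from parent A
        else:
            src = pool[int(rng.integers(len(pool)))]
            seq = src.seq
        if i in chimera_slots:
            pass  # chimeras stay clean so the breakpoint is the only signal
        else:
            n_err = rng.binomial(L, cfg.clone_error_rate)
            if n_err:
                cols = rng.choice(L, size=n_err, replace=False)
                seq = _apply_errors(seq, cols, rng, cfg.methylation_bias)
        if is_pseudo[i] and i not in chimera_slots:
            sub_cols = rng.choice(s58_mutable, size=min(cfg.pseudogene_58s_subs, len(s58_mutable)), replace=False)
            seq = _apply_errors(seq, sub_cols - 1, rng, 1.0)
            gc_cols = np.array(
                [c for c in mutable_all if seq[c - 1] in "GC" and not s58_start <= c <= s58_end]
            )
            if len(gc_cols) and cfg.gc_shift_subs:
                take = rng.choice(gc_cols, size=min(cfg.gc_shift_subs, len(gc_cols)), replace=False)
                seq = _apply_errors(seq, take - 1, rng, 1.0)
            pseudo_ids.append(cid)
        clones.append(SequenceRecord(cid, seq, library_id, Role.CLONE))
    truth.pseudogene_clones[library_id] = tuple(pseudo_ids)
    truth.chimera_clones[library_id] = chimera_info
    return clones, truth


def _apply_errors(seq: str, cols, rng: np.random.Generator, methylation_bias: float) -> str:
    """Per-base errors; with probability ``methylation_bias`` a C->T or G->A
    deamination-type change, otherwise a random different base."""
    out = list(seq)
    for c in cols:
        base = out[int(c)]
        if base not in "ACGT":
            continue
        if base in "CG" and rng.random() < methylation_bias:
            out[int(c)] = "T" if base == "C" else "A"
        else:
            choices = [b for b in "ACGT" if b != base]
            out[int(c)] = str(rng.choice(choices))
    return "".join(out)


def gen_direct_record(pool, cfg: SimConfig, record_id: str, minor_threshold: float = 0.25,
                      group: str | None = None) -> SequenceRecord:
    """Direct-Sanger emulation: IUPAC consensus of the copy pool (variants
    below the minor-peak threshold vanish, as in a real trace)."""
    rec = call_consensus(pool, minor_threshold, record_id)
    return SequenceRecord(rec.id, rec.seq, group, Role.UNKNOWN)


def gen_structure_template(cfg: SimConfig, seq: str) -> StructureTemplate:
    """A hairpin-stem pairing map over the given sequence, emulating folded
    spacer transcripts: several helices per region pairing the flanks of
    each hairpin; roughly half of ITS1 and two-thirds of ITS2 end up paired."""
    regions = cfg.regions()
    pairs: set[tuple[int, int]] = set()

    def add_hairpins(start: int, end: int, n_hairpins: int, stem: int) -> None:
        span = end - start + 1
        width = span // n_hairpins
        for h in range(n_hairpins):
            lo = start + h * width
            hi = min(lo + width - 1, end)
            s = min(stem, (hi - lo - 3) // 2)
            for k in range(s):
                pairs.add((lo + k, hi - k))

    s1, e1 = regions.spans["ITS1"]
    s5, e5 = regions.spans["5.8S"]
    s2, e2 = regions.spans["ITS2"]
    add_hairpins(s1, e1, 6, 12)  # six ITS1 hairpins
    add_hairpins(s5, e5, 2, 10)
    add_hairpins(s2, e2, 4, 18)  # four ITS2 hairpins, more tightly paired
    return StructureTemplate(seq, frozenset(pairs), dict(regions.spans))


# ---------------------------------------------------------------------------
# landmarks


def default_mean_shapes() -> dict[str, np.ndarray]:
    """Three leaf-like 14-landmark mean shapes (apex + base on the midline,
    six bilateral pairs), bilaterally symmetric, differing in lobe
    dissection depth."""

    def leaf(lobe: float, spread: float) -> np.ndarray:
        ys = np.linspace(0.75, -0.55, 6)
        widths = np.array([0.30, 0.55, 0.65, 0.60, 0.45, 0.25]) * spread
        depth = np.array([0.0, lobe, 0.0, lobe, 0.0, lobe / 2])
        left = np.column_stack([-(widths - depth), ys])
        right = np.column_stack([(widths - depth), ys])
        pts = np.vstack([[0.0, 1.0], left, [0.0, -1.0], right])
        return pts - pts.mean(axis=0)

    return {
        "notabilis": leaf(0.22, 1.00),
        "hybrid": leaf(0.30, 0.92),
        "variabilis": leaf(0.12, 1.10),
    }


#: landmark index layout matching :func:`default_mean_shapes`
LANDMARK_PAIRING = [(1, 8), (2, 9), (3, 10), (4, 11), (5, 12), (6, 13)]
LANDMARK_MIDLINE = [0, 7]


def gen_landmarks(cfg: SimConfig, rng: np.random.Generator | None = None,
                  mean_shapes: dict[str, np.ndarray] | None = None):
    """Leaf landmark dataset: per group, mean shape + isotropic Gaussian
    landmark noise, then a random similarity transform per specimen.
    Returns (configs, truth)."""
    rng = rng or np.random.default_rng(cfg.seed)
    if cfg.landmark_sigma <= 0:
        raise ValueError("landmark noise sigma must be positive")
    shapes = mean_shapes or default_mean_shapes()
    missing = [g for g in cfg.landmark_groups if g not in shapes]
    if missing:
        raise ValueError(f"no mean shape for groups: {missing}")
    truth = SimTruth(mean_shapes={g: np.asarray(shapes[g], dtype=float) for g in cfg.landmark_groups})
    configs = []
    for group, n in cfg.landmark_groups.items():
        mean = np.asarray(shapes[group], dtype=float)
        for i in range(n):
            noisy = mean + rng.normal(0.0, cfg.landmark_sigma, size=mean.shape)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            scale = rng.uniform(0.5, 2.0)
            shift = rng.uniform(-5, 5, size=2)
            coords = noisy @ rot.T * scale + shift
            configs.append(LandmarkConfiguration(f"{group}_{i + 1:03d}", group, coords))
    return configs, truth


# ---------------------------------------------------------------------------
# whole-study bundle


@dataclass
class SyntheticStudy:
    cfg: SimConfig
    regions: RegionAnnotation
    template: StructureTemplate
    maternal_pool: list[SequenceRecord]
    paternal_pool: list[SequenceRecord]
    hybrid_pool: list[SequenceRecord]
    libraries: dict[str, list[SequenceRecord]]
    direct: dict[str, SequenceRecord]
    landmarks: list[LandmarkConfiguration]
    truth: SimTruth

    def library_alignment(self, name: str) -> AlignedSet:
        return AlignedSet.from_records(self.libraries[name])


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate the full synthetic study under one seed: parents, hybrid,
    clone libraries (maternal 'S', paternal 'N', hybrid 'X'), direct-Sanger
    consensus records, a structure template on the maternal consensus, and
    the leaf landmark dataset."""
    rng = np.random.default_rng(cfg.seed)
    maternal, paternal, truth = gen_parents(cfg, rng)
    hybrid = gen_hybrid(maternal, paternal, cfg)
    parents_cons = (maternal[-1], paternal[-1])  # variant-free consensus copies
    libraries = {}
    for name, pool in (("S", maternal), ("N", paternal), ("X", hybrid)):
        lib_cfg = cfg if name == "X" else SimConfig(**{**cfg.__dict__, "n_chimeras": 0})
        clones, t = gen_clone_library(pool, lib_cfg, rng, name, parents=parents_cons)
        libraries[name] = clones
        truth.pseudogene_clones.update(t.pseudogene_clones)
        truth.chimera_clones.update(t.chimera_clones)
    direct = {
        "maternal": gen_direct_record(maternal, cfg, "direct_maternal", group="maternal"),
        "paternal": gen_direct_record(paternal, cfg, "direct_paternal", group="paternal"),
        "hybrid": gen_direct_record(hybrid, cfg, "direct_hybrid", group="hybrid"),
    }
    landmarks, lm_truth = gen_landmarks(cfg, rng)
    truth.mean_shapes = lm_truth.mean_shapes
    template = gen_structure_template(cfg, maternal[-1].seq)
    return SyntheticStudy(
        cfg=cfg,
        regions=cfg.regions(),
        template=template,
        maternal_pool=maternal,
        paternal_pool=paternal,
        hybrid_pool=hybrid,
        libraries=libraries,
        direct=direct,
        landmarks=landmarks,
        truth=truth,
    )
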