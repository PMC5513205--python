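"""Synthetic paired metagenome/metaproteome cohorts with planted effects.

Real paired MG/MP data for a cohort are expensive and rarely deposited in a
directly reusable form, so every downstream stage of this package is
exercised on simulated annotation records whose ground truth is known.  The
generative model:

1.  Each subject's community composition (genus proportions) is drawn from a
    Dirichlet centred on the cohort base proportions with concentration
    ``taxon_dispersion`` — the minimal model of inter-individual
    compositional variation.
2.  The joint (genus, KO) expectation is composition x per-genus function
    profile.  Both omic layers observe the *same* underlying community.
3.  The MP expectation is the MG expectation times ``10**effect`` per
    feature, renormalized.  Because proportions are compositional, planting
    an effect on one feature slightly shifts all others; recovery tests must
    therefore compare against the generator's post-normalization expectation
    (see :func:`expected_log_ratios`).
4.  Optionally, each subject's per-layer functional expectation is itself
    jittered by a Dirichlet (``mg_function_concentration`` /
    ``mp_function_concentration``); giving the MP layer a finite (smaller)
    concentration encodes the higher plasticity of expressed proteins
    relative to gene potential.
5.  Unit counts per layer are multinomial at the layer's depth, so each
    subject/layer total equals the depth exactly.

Records are returned as a tidy DataFrame (one row per observed
(subject, layer, genus, KO) cell, ``weight`` = unit count) and round-trip
through a TSV dialect whose ``taxon_path`` column is a semicolon-joined
lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .taxonomy import TaxonomyTree, build_taxonomy

__all__ = [
    "ConfigError",
    "CohortSpec",
    "generate_cohort",
    "null_cohort",
    "expected_profiles",
    "expected_log_ratios",
    "default_taxonomy",
    "default_cohort_spec",
    "attribution_demo_spec",
    "null_taxonomy",
    "read_records",
    "write_records",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = ["subject", "layer", "unit", "taxon", "function", "weight"]

_PROB_TOL = 1e-9


class ConfigError(ValueError):
    """Invalid cohort specification."""


@dataclass
class CohortSpec:
    """Full description of a simulated two-layer cohort.

    Parameters
    ----------
    n_subjects
        Cohort size; the emulated study design uses 15.
    taxa
        Genus-level taxon ids (must resolve in the companion taxonomy).
    functions
        KO (KEGG ortholog) identifiers.
    base_taxon_props
        Cohort-level expected genus proportions (sum to 1).
    taxon_dispersion
        Dirichlet concentration for between-subject compositional noise;
        ``inf`` disables subject noise.  Default 10 reproduces a realistic
        gut-cohort spread (phylum shares ranging over tens of percent).
    function_profile
        Map genus -> probability vector over ``functions`` (each sums to 1).
    mg_depth, mp_depth
        Units (reads / spectra) per subject per layer.  Defaults of 200,000
        and 7,000 mirror typical subsampled shotgun-read and PSM yields.
    effect_log_ratio
        Planted true log10 MP/MG offsets keyed by KO id, genus id, or a
        (genus, KO) pair; offsets for matching keys add.  0 = null.
    mg_function_concentration, mp_function_concentration
        Optional per-subject, per-layer Dirichlet jitter of the functional
        expectation; ``None`` disables.  The default (MP jittered at
        concentration 50, MG not jittered) encodes expressed functions being
        more variable between subjects than the gene potential.
    unannotated_fraction
        Fraction of units whose function is masked to ``"unannotated"``,
        emulating annotation-yield gaps.
    seed
        Base seed; identical spec + seed gives byte-identical records.
    """

    taxa: list[str]
    functions: list[str]
    base_taxon_props: np.ndarray
    function_profile: dict[str, np.ndarray]
    n_subjects: int = 15
    taxon_dispersion: float = 10.0
    mg_depth: int = 200_000
    mp_depth: int = 7_000
    effect_log_ratio: dict = field(default_factory=dict)
    mg_function_concentration: float | None = None
    mp_function_concentration: float | None = 50.0
    unannotated_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_taxon_props = np.asarray(self.base_taxon_props, dtype=float)
        self.function_profile = {
            t: np.asarray(v, dtype=float) for t, v in self.function_profile.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.mg_depth <= 0 or self.mp_depth <= 0:
            raise ConfigError("depths must be > 0")
        if len(self.base_taxon_props) != len(self.taxa):
            raise ConfigError("base_taxon_props length mismatch with taxa")
        _check_prob_vector(self.base_taxon_props, "base_taxon_props")
        if set(self.function_profile) != set(self.taxa):
            raise ConfigError("function_profile must have one entry per taxon")
        for t, v in self.function_profile.items():
            if len(v) != len(self.functions):
                raise ConfigError(f"function_profile[{t}] length mismatch")
            _check_prob_vector(v, f"function_profile[{t}]")
        if not 0.0 <= self.unannotated_fraction < 1.0:
            raise ConfigError("unannotated_fraction must be in [0, 1)")
        if self.taxon_dispersion <= 0:
            raise ConfigError("taxon_dispersion must be > 0 (or inf)")
        known = set(self.taxa) | set(self.functions)
        for key in self.effect_log_ratio:
            if isinstance(key, tuple):
                t, k = key
                if t not in self.taxa or k not in self.functions:
                    raise ConfigError(f"effect key {key!r} not found")
            elif key not in known:
                raise ConfigError(f"effect key {key!r} not found")

    # -- serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "n_subjects": self.n_subjects,
            "taxa": list(self.taxa),
            "functions": list(self.functions),
            "base_taxon_props": [float(x) for x in self.base_taxon_props],
            "function_profile": {
                t: [float(x) for x in v] for t, v in self.function_profile.items()
            },
            "taxon_dispersion": float(self.taxon_dispersion),
            "mg_depth": self.mg_depth,
            "mp_depth": self.mp_depth,
            "effect_log_ratio": {
                ("|".join(k) if isinstance(k, tuple) else k): float(v)
                for k, v in self.effect_log_ratio.items()
            },
            "mg_function_concentration": self.mg_function_concentration,
            "mp_function_concentration": self.mp_function_concentration,
            "unannotated_fraction": self.unannotated_fraction,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"spec file {path} is not a mapping")
        allowed = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(doc) - allowed
        if unknown:
            raise ConfigError(f"unknown spec keys: {sorted(unknown)}")
        effects = {}
        for k, v in (doc.pop("effect_log_ratio", {}) or {}).items():
            effects[tuple(k.split("|")) if "|" in k else k] = float(v)
        try:
            return cls(effect_log_ratio=effects, **doc)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _check_prob_vector(v: np.ndarray, label: str) -> None:
    if np.any(v < 0):
        raise ConfigError(f"{label} has negative entries")
    s = float(v.sum())
    if abs(s - 1.0) > _PROB_TOL:
        raise ConfigError(f"{label} sums to {s}, expected 1")
    if s == 0 or np.all(v == 0):
        raise ConfigError(f"{label} is degenerate (all zero)")


# ---------------------------------------------------------------------------
# Generation


def _effect_matrix(spec: CohortSpec) -> np.ndarray:
    """Per-(taxon, function) total log10 effect, taxa x functions."""
    e = np.zeros((len(spec.taxa), len(spec.functions)))
    t_idx = {t: i for i, t in enumerate(spec.taxa)}
    f_idx = {f: j for j, f in enumerate(spec.functions)}
    for key, val in spec.effect_log_ratio.items():
        if isinstance(key, tuple):
            e[t_idx[key[0]], f_idx[key[1]]] += val
        elif key in t_idx:
            e[t_idx[key], :] += val
        else:
            e[:, f_idx[key]] += val
    return e


def _joint_expectation(spec: CohortSpec, taxon_props: np.ndarray) -> np.ndarray:
    """taxa x functions joint probability for one subject's community."""
    prof = np.stack([spec.function_profile[t] for t in spec.taxa])
    joint = taxon_props[:, None] * prof
    total = joint.sum()
    if total <= 0:
        raise ConfigError("degenerate joint expectation (all zero)")
    return joint / total


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw annotation records for every subject and both layers.

    Returns a DataFrame with columns ``subject, layer, unit, taxon,
    function, weight`` where ``weight`` counts the units (reads or spectra)
    observed for that (genus, KO) cell.  Each subject/layer's total weight
    equals the layer depth exactly.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    effects = _effect_matrix(spec)
    mult = 10.0 ** effects
    n_t, n_f = len(spec.taxa), len(spec.functions)
    subjects = [f"S{i + 1:02d}" for i in range(spec.n_subjects)]
    # "unannotated" behaves as an extra function column per taxon
    taxa_arr = np.repeat(spec.taxa, n_f + 1)
    func_arr = np.tile(np.array(spec.functions + ["unannotated"]), n_t)

    parts: list[pd.DataFrame] = []
    for subj in subjects:
        if math.isinf(spec.taxon_dispersion):
            props = spec.base_taxon_props
        else:
            alpha = spec.base_taxon_props * spec.taxon_dispersion
            props = _dirichlet(rng, alpha)
        joint = _joint_expectation(spec, props)
        mg_p = joint.ravel()
        mp_joint = joint * mult
        mp_p = mp_joint.ravel() / mp_joint.sum()
        for layer, p, depth, conc in (
            ("MG", mg_p, spec.mg_depth, spec.mg_function_concentration),
            ("MP", mp_p, spec.mp_depth, spec.mp_function_concentration),
        ):
            if conc is not None:
                p = _dirichlet(rng, p * conc)
            counts = rng.multinomial(depth, p).reshape(n_t, n_f)
            if spec.unannotated_fraction > 0:
                masked = rng.binomial(counts, spec.unannotated_fraction)
                counts = counts - masked
                unann = masked.sum(axis=1)
            else:
                unann = np.zeros(n_t, dtype=np.int64)
            full = np.concatenate([counts, unann[:, None]], axis=1).ravel()
            (nz,) = np.nonzero(full)
            units = [f"{subj}:{layer}:{u:06d}" for u in range(len(nz))]
            parts.append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "layer": layer,
                        "unit": units,
                        "taxon": taxa_arr[nz],
                        "function": func_arr[nz],
                        "weight": full[nz].astype(np.int64),
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)[RECORD_COLUMNS]


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    # rng.dirichlet rejects zero concentrations; gamma(0) == 0 keeps
    # zero-probability cells at exactly zero.
    g = rng.gamma(np.maximum(alpha, 0.0), 1.0)
    total = g.sum()
    if total == 0:
        raise ConfigError("degenerate Dirichlet draw (all-zero concentration)")
    return g / total


def null_cohort(
    n_subjects: int,
    n_features: int,
    depth: int,
    seed: int,
    effect_log_ratio: dict | None = None,
    taxon_dispersion: float = 500.0,
) -> tuple[pd.DataFrame, TaxonomyTree]:
    """Two-layer cohort with uniform base proportions and (by default) no effects.

    Each feature is a distinct genus carrying a distinct KO, split across two
    synthetic phyla, so the same records support taxon-level, KO-level and
    partition analyses under the global null.  The default concentration of
    500 gives every feature a between-subject CV of roughly 45% at 100
    features — every subject carries every feature, as in real cohorts'
    shared core.  ``effect_log_ratio`` turns the wrapper into a
    planted-effect harness.  Returns (records, taxonomy).
    """
    if n_features < 2:
        raise ConfigError("n_features must be >= 2")
    if depth <= 0:
        raise ConfigError("depth must be > 0")
    taxa = [f"g__T{i:03d}" for i in range(n_features)]
    functions = [f"K{i:05d}" for i in range(n_features)]
    profile = {t: np.eye(n_features)[i] for i, t in enumerate(taxa)}
    spec = CohortSpec(
        taxa=taxa,
        functions=functions,
        base_taxon_props=np.full(n_features, 1.0 / n_features),
        function_profile=profile,
        n_subjects=n_subjects,
        taxon_dispersion=taxon_dispersion,
        mg_depth=depth,
        mp_depth=depth,
        effect_log_ratio=dict(effect_log_ratio or {}),
        mg_function_concentration=None,
        mp_function_concentration=None,
        seed=seed,
    )
    return generate_cohort(spec), null_taxonomy(n_features)


def null_taxonomy(n_features: int) -> TaxonomyTree:
    """Minimal two-phylum taxonomy matching :func:`null_cohort` genera."""
    edges = [
        ("p__PhylumA", "root", "phylum", "PhylumA"),
        ("p__PhylumB", "root", "phylum", "PhylumB"),
    ]
    for i in range(n_features):
        phylum = "p__PhylumA" if i < n_features // 2 else "p__PhylumB"
        edges.append((f"g__T{i:03d}", phylum, "genus", f"T{i:03d}"))
    return build_taxonomy(edges)


# ---------------------------------------------------------------------------
# Generator expectations (the simulation's own ground truth)


def expected_profiles(spec: CohortSpec) -> tuple[pd.Series, pd.Series]:
    """Expected MG and MP (genus, KO) proportions at the cohort base composition.

    Subject-level Dirichlet noise perturbs these per subject; across the
    cohort they are the first-order expectation used as the planted truth in
    recovery tests.
    """
    joint = _joint_expectation(spec, spec.base_taxon_props)
    mp_joint = joint * 10.0 ** _effect_matrix(spec)
    idx = pd.MultiIndex.from_product(
        [spec.taxa, spec.functions], names=["taxon", "function"]
    )
    mg = pd.Series(joint.ravel(), index=idx)
    mp = pd.Series(mp_joint.ravel() / mp_joint.sum(), index=idx)
    return mg, mp


def expected_log_ratios(spec: CohortSpec, level: str = "KO") -> pd.Series:
    """Generator-truth mean log10(MP/MG) per feature at the requested level.

    ``level`` is ``"KO"``, ``"taxon"`` (genus), or ``"joint"``.  Renormalized
    MP proportions mean even zero-effect features carry a small offset
    (compositional closure); this is the correct comparison target for
    planted-effect recovery.
    """
    mg, mp = expected_profiles(spec)
    if level == "KO":
        mg, mp = mg.groupby(level="function").sum(), mp.groupby(level="function").sum()
    elif level == "taxon":
        mg, mp = mg.groupby(level="taxon").sum(), mp.groupby(level="taxon").sum()
    elif level != "joint":
        raise ValueError(f"unknown level: {level!r}")
    return np.log10(mp / mg)


# ---------------------------------------------------------------------------
# Default study-condition community


def default_taxonomy() -> TaxonomyTree:
    """Gut-community taxonomy: 13 genera under 5 phyla with full lineages."""
    rows = [
        # (genus, family, order, class, phylum)
        ("g__Faecalibacterium", "f__Ruminococcaceae", "o__Clostridiales",
         "c__Clostridia", "p__Firmicutes"),
        ("g__Ruminococcus", "f__Ruminococcaceae", "o__Clostridiales",
         "c__Clostridia", "p__Firmicutes"),
        ("g__Coprococcus", "f__Lachnospiraceae", "o__Clostridiales",
         "c__Clostridia", "p__Firmicutes"),
        ("g__Butyrivibrio", "f__Lachnospiraceae", "o__Clostridiales",
         "c__Clostridia", "p__Firmicutes"),
        ("g__Dialister", "f__Veillonellaceae", "o__Selenomonadales",
         "c__Negativicutes", "p__Firmicutes"),
        ("g__Streptococcus", "f__Streptococcaceae", "o__Lactobacillales",
         "c__Bacilli", "p__Firmicutes"),
        ("g__Bacteroides", "f__Bacteroidaceae", "o__Bacteroidales",
         "c__Bacteroidia", "p__Bacteroidetes"),
        ("g__Prevotella", "f__Prevotellaceae", "o__Bacteroidales",
         "c__Bacteroidia", "p__Bacteroidetes"),
        ("g__Alistipes", "f__Rikenellaceae", "o__Bacteroidales",
         "c__Bacteroidia", "p__Bacteroidetes"),
        ("g__Parabacteroides", "f__Porphyromonadaceae", "o__Bacteroidales",
         "c__Bacteroidia", "p__Bacteroidetes"),
        ("g__Bifidobacterium", "f__Bifidobacteriaceae", "o__Bifidobacteriales",
         "c__Actinobacteria", "p__Actinobacteria"),
        ("g__Escherichia", "f__Enterobacteriaceae", "o__Enterobacterales",
         "c__Gammaproteobacteria", "p__Proteobacteria"),
        ("g__Akkermansia", "f__Akkermansiaceae", "o__Verrucomicrobiales",
         "c__Verrucomicrobiae", "p__Verrucomicrobia"),
    ]
    edges: dict[str, tuple[str, str, str, str]] = {}
    ranks = ["genus", "family", "order", "class", "phylum"]
    for row in rows:
        chain = list(row) + ["k__Bacteria", "root"]
        chain_ranks = ranks + ["superkingdom", "root"]
        for child, par, rk in zip(chain[:-1], chain[1:], chain_ranks[:-1]):
            edges[child] = (child, par, rk, child.split("__", 1)[-1])
    edges["k__Bacteria"] = ("k__Bacteria", "root", "superkingdom", "Bacteria")
    return build_taxonomy(edges.values())


# Carbohydrate-metabolism pathway structure shared with the attribution module:
# (pathway, [KO ids], cohort-level expression weight).  Weights emulate the
# observed pathway shares of total carbohydrate metabolism (~50% glycolysis,
# 12% butyrogenesis, 7% interconversion, 6% sugar transport, 3% propionogenesis,
# 1% acetogenesis, remainder degradation/catabolism).
DEFAULT_PATHWAY_WEIGHTS = [
    ("Polysaccharide degradation", ["K01176", "K01181", "K01198"], 0.12),
    ("Sugar transport", ["K10112", "K10117", "K21572"], 0.06),
    ("Aldose/ketose interconversion", ["K01805", "K01818"], 0.07),
    ("Carbohydrate catabolic pathways", ["K00615", "K00616", "K01625"], 0.09),
    ("Glycolysis", ["K00134", "K00927", "K01689", "K01810", "K00850"], 0.50),
    ("Acetogenesis", ["K00625", "K00925"], 0.01),
    ("Propionogenesis", ["K01847", "K05606"], 0.03),
    ("Butyrogenesis", ["K00626", "K00074", "K00248", "K01034"], 0.12),
]


def _pathway_function_base() -> tuple[list[str], np.ndarray]:
    functions: list[str] = []
    weights: list[float] = []
    for _, kos, w in DEFAULT_PATHWAY_WEIGHTS:
        functions.extend(kos)
        weights.extend([w / len(kos)] * len(kos))
    return functions, np.asarray(weights)


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default simulated gut cohort: 15 subjects, F/B-dominated community.

    Base genus proportions put ~45% of units under Firmicutes and ~49% under
    Bacteroidetes, with minor Actinobacteria, Proteobacteria, and
    Verrucomicrobia.  All genera share the pathway-weighted base function
    profile, with genus-specific enrichments (butyrogenesis concentrated in
    Faecalibacterium and other Clostridiales, degradation/transport in
    Bacteroidetes, interconversion in Bifidobacterium).
    """
    taxa = [
        "g__Faecalibacterium", "g__Ruminococcus", "g__Coprococcus",
        "g__Butyrivibrio", "g__Dialister", "g__Streptococcus",
        "g__Bacteroides", "g__Prevotella", "g__Alistipes", "g__Parabacteroides",
        "g__Bifidobacterium", "g__Escherichia", "g__Akkermansia",
    ]
    props = np.array([
        0.18, 0.10, 0.06, 0.04, 0.04, 0.03,      # Firmicutes: 0.45
        0.25, 0.12, 0.07, 0.05,                   # Bacteroidetes: 0.49
        0.03, 0.02, 0.01,
    ])
    functions, base_w = _pathway_function_base()
    fidx = {f: j for j, f in enumerate(functions)}

    def tweak(**boost: float) -> np.ndarray:
        w = base_w.copy()
        for pathway, kos, _ in DEFAULT_PATHWAY_WEIGHTS:
            if pathway in boost:
                for k in kos:
                    w[fidx[k]] *= boost[pathway]
        return w / w.sum()

    butyrogenic = tweak(Butyrogenesis=3.0)
    degrader = tweak(**{"Polysaccharide degradation": 2.5, "Sugar transport": 2.0})
    profile = {t: base_w / base_w.sum() for t in taxa}
    profile["g__Faecalibacterium"] = butyrogenic
    profile["g__Butyrivibrio"] = butyrogenic
    profile["g__Coprococcus"] = tweak(Butyrogenesis=2.0)
    profile["g__Dialister"] = tweak(Propionogenesis=4.0)
    profile["g__Bacteroides"] = degrader
    profile["g__Prevotella"] = degrader
    profile["g__Bifidobacterium"] = tweak(
        **{"Aldose/ketose interconversion": 3.0,
           "Carbohydrate catabolic pathways": 2.0}
    )
    params = dict(
        taxa=taxa,
        functions=functions,
        base_taxon_props=props,
        function_profile=profile,
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


def attribution_demo_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Cohort whose planted truth matches the headline attribution shares.

    Every genus shares the identical pathway-weighted function profile, so
    pathway shares equal the configured weights exactly, and base genus
    proportions place 46/51/3% of units under Firmicutes, Bacteroidetes, and
    Actinobacteria respectively.
    """
    taxa = [
        "g__Faecalibacterium", "g__Ruminococcus", "g__Coprococcus",
        "g__Bacteroides", "g__Prevotella", "g__Alistipes",
        "g__Bifidobacterium",
    ]
    props = np.array([0.24, 0.12, 0.10, 0.30, 0.13, 0.08, 0.03])
    functions, base_w = _pathway_function_base()
    profile = {t: base_w / base_w.sum() for t in taxa}
    params = dict(
        taxa=taxa,
        functions=functions,
        base_taxon_props=props,
        function_profile=profile,
        mp_function_concentration=None,
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


# ---------------------------------------------------------------------------
# Record I/O (TSV dialect: subject, layer, unit, taxon_path, ko, weight)


def write_records(records: pd.DataFrame, path, tree: TaxonomyTree | None = None) -> None:
    """Write records TSV; with a tree, taxon ids expand to full lineage paths."""
    out = records.copy()
    if tree is not None:
        paths = {t: tree.lineage_string(t) for t in out["taxon"].unique() if t in tree}
        out["taxon"] = out["taxon"].map(lambda t: paths.get(t, t))
    out = out.rename(columns={"taxon": "taxon_path", "function": "ko"})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_records(path) -> pd.DataFrame:
    """Read a records TSV; lineage paths collapse back to their deepest taxon."""
    df = pd.read_csv(path, sep="\t", dtype={"weight": np.int64})
    required = {"subject", "layer", "unit", "taxon_path", "ko", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"records file {path} missing columns {sorted(missing)}")
    df["taxon_path"] = df["taxon_path"].str.split(";").str[-1]
    return df.rename(columns={"taxon_path": "taxon", "ko": "function"})[RECORD_COLUMNS]
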