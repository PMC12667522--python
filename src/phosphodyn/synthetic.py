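"""Synthetic stage-series and knockout phosphoproteomic experiments.

The generator emulates a TMT-style design: four ordered developmental
stages with four replicates each, a protein intensity table, a phosphosite
table coupled to protein abundance, and a kinase-substrate relation table
with planted module-specific kinases.  Ground truth (site module labels,
planted kinase activities, expected stage means, knockout labels) is
returned alongside so every downstream inference step can be scored.

Sampling model (all draws from one seeded generator):

* protein cell: exp(base_g + stage_effect_{g,s} + N(0, protein_cv))
* site cell:    protein cell x stoichiometry_s x 2^traj_k(s) x exp(N(0, noise_sd))

so a site co-varies with its protein and calibration is meaningful; on the
relative-abundance scale a module site's expected stage profile is its
trajectory multiplier normalized to mean 1.  Zeros are sprinkled at
``zero_rate``; a ``missing_protein_rate`` fraction of proteins is withheld
from the protein table (their sites exercise the site-only fallback).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (ConfigurationError, KSRTable, PhosphoSites, QuantMatrix,
                   SampleDesign)
from .motifs import extract_window

logger = logging.getLogger("phosphodyn")

SPERMIOGENESIS_STAGES = ("step1-2", "step3-4", "step5-6", "step13-14")

#: the four default temporal patterns (log2 stage effects): gradual decrease,
#: dip at the third stage, peak at the third stage, peak at the last stage
DEFAULT_TRAJECTORIES = (
    (1.5, 0.5, -0.5, -1.5),
    (0.5, 0.5, -1.5, 0.5),
    (-0.5, -0.5, 1.5, -0.5),
    (-0.5, -0.5, -0.5, 1.5),
)

DEFAULT_SITES_PER_PROTEIN = {1: 0.45, 2: 0.20, 3: 0.12, 4: 0.08, 5: 0.05,
                             6: 0.04, 7: 0.03, 8: 0.015, 9: 0.01, 10: 0.005}

# rough vertebrate amino-acid background for generated protein sequences
_AA = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_FREQ = np.array([0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068,
                     0.058, 0.099, 0.025, 0.045, 0.039, 0.034, 0.042, 0.081,
                     0.062, 0.068, 0.011, 0.014])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass
class SyntheticConfig:
    """Fully specifies one synthetic experiment; the seed fixes its bytes."""

    n_stages: int = 4
    n_replicates: int = 4
    n_proteins: int = 1000
    n_sites: int = 2000
    sites_per_protein_dist: dict = field(
        default_factory=lambda: dict(DEFAULT_SITES_PER_PROTEIN))
    module_trajectories: tuple = DEFAULT_TRAJECTORIES
    module_site_fractions: tuple = (0.15, 0.15, 0.15, 0.15)
    noise_sd: float = 0.5
    protein_cv: float = 0.15
    protein_stage_sd: float = 0.25
    zero_rate: float = 0.01
    missing_protein_rate: float = 0.05
    n_kinases: int = 20
    substrates_per_kinase: int = 100
    planted_active: dict | None = None      # module (1-based) -> (kinase, factor)
    loc_prob_dist: tuple = (0.85, 40.0, 2.0, 2.0, 2.0)
    residue_probs: tuple = (0.897, 0.099, 0.003)
    motif_pro_plus1: float = 0.3
    protein_log_mean: float = 16.0
    protein_log_sd: float = 1.0
    stoich_log_mean: float = -2.3
    stoich_log_sd: float = 0.5
    seq_length_range: tuple = (200, 800)
    stage_labels: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_stages", "n_replicates", "n_proteins", "n_sites",
                     "n_kinases", "substrates_per_kinase"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_stages < 2:
            raise ConfigurationError("need at least 2 stages")
        self.module_trajectories = tuple(tuple(float(v) for v in t)
                                         for t in self.module_trajectories)
        self.module_site_fractions = tuple(float(f)
                                           for f in self.module_site_fractions)
        if len(self.module_site_fractions) != len(self.module_trajectories):
            raise ConfigurationError("one site fraction per module trajectory")
        for t in self.module_trajectories:
            if len(t) != self.n_stages:
                raise ConfigurationError("trajectory length must equal n_stages")
        for name in ("zero_rate", "missing_protein_rate", "motif_pro_plus1"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if any(f < 0 or f > 1 for f in self.module_site_fractions):
            raise ConfigurationError("module site fractions must lie in [0, 1]")
        if sum(self.module_site_fractions) > 1 + 1e-12:
            raise ConfigurationError("module site fractions sum above 1")
        for name in ("noise_sd", "protein_cv", "protein_stage_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        total = sum(self.sites_per_protein_dist.values())
        if total <= 0:
            raise ConfigurationError("sites_per_protein_dist must have mass")
        self.sites_per_protein_dist = {
            int(k): v / total for k, v in self.sites_per_protein_dist.items()}
        if self.stage_labels is None:
            self.stage_labels = (SPERMIOGENESIS_STAGES
                                 if self.n_stages == 4 else
                                 tuple(f"stage{i + 1}"
                                       for i in range(self.n_stages)))
        self.stage_labels = tuple(self.stage_labels)
        if len(self.stage_labels) != self.n_stages:
            raise ConfigurationError("stage_labels length must equal n_stages")
        if self.planted_active is None:
            self.planted_active = {
                k + 1: (f"KIN{k + 1:03d}", 5.0)
                for k in range(len(self.module_trajectories))}
        self.planted_active = {int(k): (str(v[0]), float(v[1]))
                               for k, v in self.planted_active.items()}
        if len(self.planted_active) > self.n_kinases:
            raise ConfigurationError("more planted kinases than n_kinases")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_trajectories"] = [list(t) for t in self.module_trajectories]
        d["planted_active"] = {str(k): [v[0], v[1]]
                               for k, v in self.planted_active.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "planted_active" in d and d["planted_active"] is not None:
            d["planted_active"] = {int(k): (v[0], float(v[1]))
                                   for k, v in d["planted_active"].items()}
        for key in ("module_trajectories", "module_site_fractions",
                    "loc_prob_dist", "residue_probs", "seq_length_range",
                    "stage_labels"):
            if key in d and d[key] is not None:
                d[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x
                               for x in d[key])
        if "sites_per_protein_dist" in d:
            d["sites_per_protein_dist"] = {
                int(k): float(v) for k, v in d["sites_per_protein_dist"].items()}
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the synthetic tables."""

    site_module: pd.Series            # site_id -> module index (0 = none)
    kinase_module: dict               # kinase -> (module, planted class)
    edges: pd.DataFrame               # the emitted KSR rows
    expected_stage_means: pd.DataFrame  # site x stage, relative-abundance scale
    ko_label: pd.Series | None = None  # site_id -> down/null (KO designs)


@dataclass
class StageExperiment:
    proteins: QuantMatrix
    sites: PhosphoSites
    ksr: KSRTable
    truth: SyntheticTruth
    sequences: dict


@dataclass
class KOExperiment:
    proteins: QuantMatrix
    sites: PhosphoSites
    truth: SyntheticTruth
    sequences: dict


def _base_structure(cfg: SyntheticConfig, rng: np.random.Generator):
    """Protein ids, site->protein assignment, sequences, residues, positions."""
    protein_ids = [f"P{i + 1:05d}" for i in range(cfg.n_proteins)]
    ks = np.array(sorted(cfg.sites_per_protein_dist))
    probs = np.array([cfg.sites_per_protein_dist[int(k)] for k in ks])
    counts = rng.choice(ks, size=cfg.n_proteins, p=probs)
    pool = np.repeat(np.arange(cfg.n_proteins), counts)
    if pool.size < cfg.n_sites:
        raise ConfigurationError(
            f"sites-per-protein pool ({pool.size}) smaller than n_sites "
            f"({cfg.n_sites}); raise n_proteins or the distribution's mean")
    chosen = rng.permutation(pool)[:cfg.n_sites]

    lengths = rng.integers(cfg.seq_length_range[0],
                           cfg.seq_length_range[1] + 1, size=cfg.n_proteins)
    seqs = [list(rng.choice(list(_AA), size=int(n), p=_AA_FREQ))
            for n in lengths]

    res_p = np.array(cfg.residue_probs, dtype=float)
    res_p = res_p / res_p.sum()
    residues = rng.choice(["S", "T", "Y"], size=cfg.n_sites, p=res_p)

    used: dict[int, set[int]] = {}
    positions = np.empty(cfg.n_sites, dtype=int)
    for i, (g, res) in enumerate(zip(chosen, residues)):
        seq = seqs[g]
        taken = used.setdefault(int(g), set())
        slots = [j for j, aa in enumerate(seq) if aa == res and j not in taken]
        if slots:
            j = int(slots[rng.integers(len(slots))])
        else:
            free = [j for j in range(len(seq)) if j not in taken]
            j = int(free[rng.integers(len(free))])
            seq[j] = res
        taken.add(j)
        positions[i] = j + 1  # 1-based
    # plant a proline-directed motif at +1 for a fraction of S/T sites
    for i, (g, res) in enumerate(zip(chosen, residues)):
        if res == "Y" or rng.random() >= cfg.motif_pro_plus1:
            continue
        j = positions[i]  # 0-based index of +1 is exactly `positions[i]`
        if j < len(seqs[g]) and j not in used[int(g)]:
            seqs[g][j] = "P"

    sequences = {pid: "".join(s) for pid, s in zip(protein_ids, seqs)}
    site_meta = pd.DataFrame({
        "protein_idx": chosen,
        "protein_id": [protein_ids[g] for g in chosen],
        "residue": residues,
        "position": positions,
    })
    site_meta["site_id"] = (site_meta["protein_id"] + "_"
                            + site_meta["residue"]
                            + site_meta["position"].astype(str))
    if site_meta["site_id"].duplicated().any():  # defensive; slots are unique
        raise RuntimeError("duplicate synthetic site ids")
    return protein_ids, site_meta, sequences


def sample_substrates(rng: np.random.Generator, module_idx: np.ndarray,
                      other_idx: np.ndarray, n_substrates: int,
                      factor: float) -> np.ndarray:
    """Draw substrate indices biased toward a module.

    Each substrate falls inside the module with probability
    min(1, factor * module fraction) — a uniform draw boosted
    ``factor``-fold — and sites are drawn without replacement within each
    side.  ``factor`` = 1 reduces to a uniform draw over all sites.
    """
    n_total = module_idx.size + other_idx.size
    if n_substrates > n_total:
        raise ConfigurationError("more substrates requested than sites")
    p_mod = min(1.0, factor * module_idx.size / n_total)
    k = int(rng.binomial(n_substrates, p_mod))
    k = min(k, module_idx.size)
    k = max(k, n_substrates - other_idx.size)
    inside = rng.choice(module_idx, size=k, replace=False)
    outside = rng.choice(other_idx, size=n_substrates - k, replace=False)
    return np.concatenate([inside, outside])


def _loc_probs(cfg: SyntheticConfig, rng: np.random.Generator, n: int
               ) -> np.ndarray:
    w_hi, a_hi, b_hi, a_lo, b_lo = cfg.loc_prob_dist
    hi = rng.random(n) < w_hi
    out = np.where(hi, rng.beta(a_hi, b_hi, size=n),
                   rng.beta(a_lo, b_lo, size=n))
    return out


def _protein_cells(cfg: SyntheticConfig, rng: np.random.Generator,
                   design: SampleDesign, stage_index: np.ndarray
                   ) -> np.ndarray:
    n_samples = len(design.samples)
    base = rng.normal(cfg.protein_log_mean, cfg.protein_log_sd, cfg.n_proteins)
    stage_eff = (rng.normal(0.0, cfg.protein_stage_sd,
                            (cfg.n_proteins, cfg.n_stages))
                 if cfg.protein_stage_sd > 0
                 else np.zeros((cfg.n_proteins, cfg.n_stages)))
    rep_noise = (rng.normal(0.0, cfg.protein_cv, (cfg.n_proteins, n_samples))
                 if cfg.protein_cv > 0
                 else np.zeros((cfg.n_proteins, n_samples)))
    return np.exp(base[:, None] + stage_eff[:, stage_index] + rep_noise)


def _apply_zeros(vals: np.ndarray, rate: float, rng: np.random.Generator
                 ) -> np.ndarray:
    if rate > 0:
        vals = np.where(rng.random(vals.shape) < rate, 0.0, vals)
    return vals


def _assemble_sites(cfg, design, site_meta, multipliers, protein_cells, rng,
                    sequences) -> pd.DataFrame:
    n_sites = len(site_meta)
    stoich = np.exp(rng.normal(cfg.stoich_log_mean, cfg.stoich_log_sd, n_sites))
    noise = (np.exp(rng.normal(0.0, cfg.noise_sd,
                               (n_sites, len(design.samples))))
             if cfg.noise_sd > 0
             else np.ones((n_sites, len(design.samples))))
    x = (protein_cells[site_meta["protein_idx"].to_numpy()]
         * stoich[:, None] * multipliers * noise)
    x = _apply_zeros(x, cfg.zero_rate, rng)
    recs = site_meta[["site_id", "protein_id", "residue", "position"]].copy()
    recs["loc_prob"] = _loc_probs(cfg, rng, n_sites)
    recs["window"] = [
        extract_window(sequences[pid], int(pos), 10)
        for pid, pos in zip(recs["protein_id"], recs["position"])]
    for j, s in enumerate(design.samples):
        recs[s] = x[:, j]
    return recs


def _emit_proteins(cfg, design, protein_ids, protein_cells, rng
                   ) -> tuple[QuantMatrix, np.ndarray]:
    missing = rng.random(cfg.n_proteins) < cfg.missing_protein_rate
    vals = _apply_zeros(protein_cells.copy(), cfg.zero_rate, rng)
    frame = pd.DataFrame(vals, index=protein_ids,
                         columns=list(design.samples))
    kept = frame.loc[~missing]
    logger.info("synthetic: emitted %d of %d proteins (%d withheld as "
                "unquantified)", len(kept), cfg.n_proteins, int(missing.sum()))
    return QuantMatrix(kept, design), missing


def generate_stage_experiment(config: SyntheticConfig) -> StageExperiment:
    """Simulate a stage-series experiment with planted temporal modules."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    design = SampleDesign.from_layout(list(cfg.stage_labels), cfg.n_replicates)
    stage_index = np.array([cfg.stage_labels.index(design.stage_of[s])
                            for s in design.samples])

    protein_ids, site_meta, sequences = _base_structure(cfg, rng)

    # module labels: counts from the configured fractions, permuted over sites
    n_sites = len(site_meta)
    labels = np.zeros(n_sites, dtype=int)
    counts = [int(round(f * n_sites)) for f in cfg.module_site_fractions]
    start = 0
    for k, n_k in enumerate(counts, start=1):
        labels[start:start + n_k] = k
        start += n_k
    labels = labels[rng.permutation(n_sites)]
    site_meta["module"] = labels

    traj = np.array(cfg.module_trajectories, dtype=float).reshape(
        len(cfg.module_trajectories), cfg.n_stages)
    mult_by_module = np.vstack([np.ones((1, cfg.n_stages)),
                                2.0 ** traj])          # row 0 = null sites
    multipliers = mult_by_module[labels][:, stage_index]

    protein_cells = _protein_cells(cfg, rng, design, stage_index)
    recs = _assemble_sites(cfg, design, site_meta, multipliers, protein_cells,
                           rng, sequences)
    proteins, _missing = _emit_proteins(cfg, design, protein_ids,
                                        protein_cells, rng)
    sites = PhosphoSites(recs, design)

    # kinase-substrate edges: planted kinases over-sample their module
    site_keys = (site_meta["protein_id"] + "_" + site_meta["residue"]
                 + site_meta["position"].astype(str)).to_numpy()
    kinases = [f"KIN{i + 1:03d}" for i in range(cfg.n_kinases)]
    planted_by_kinase = {v[0]: (mod, v[1])
                         for mod, v in cfg.planted_active.items()}
    edge_rows = []
    kinase_module = {}
    n_sub = min(cfg.substrates_per_kinase, n_sites)
    for kin in kinases:
        if kin in planted_by_kinase:
            mod, factor = planted_by_kinase[kin]
            idx = sample_substrates(rng, np.where(labels == mod)[0],
                                    np.where(labels != mod)[0], n_sub, factor)
            kinase_module[kin] = (mod, "hyperrepresented")
        else:
            idx = rng.choice(n_sites, size=n_sub, replace=False)
            kinase_module[kin] = (0, "decoy")
        for i in idx:
            edge_rows.append((kin, site_meta["protein_id"].iat[i],
                              site_meta["residue"].iat[i],
                              int(site_meta["position"].iat[i]), "medium"))
    edges = pd.DataFrame(edge_rows, columns=["kinase", "protein_id",
                                             "residue", "position", "tier"])

    expected = pd.DataFrame(
        mult_by_module[labels] / mult_by_module[labels].mean(axis=1)[:, None],
        index=site_meta["site_id"], columns=list(cfg.stage_labels))
    truth = SyntheticTruth(
        site_module=pd.Series(labels, index=site_meta["site_id"],
                              name="module"),
        kinase_module=kinase_module, edges=edges,
        expected_stage_means=expected)
    return StageExperiment(proteins=proteins, sites=sites,
                           ksr=KSRTable(edges), truth=truth,
                           sequences=sequences)


def generate_ko_experiment(config: SyntheticConfig, frac_down: float = 0.15,
                           effect: float = 2.0) -> KOExperiment:
    """Simulate a two-group (control vs knockout) experiment.

    A ``frac_down`` fraction of sites is planted with an expected
    KO/control relative abundance of 1/effect; all other sites are null.
    """
    cfg = config
    if not 0 <= frac_down <= 1:
        raise ConfigurationError("frac_down must lie in [0, 1]")
    if effect <= 1:
        raise ConfigurationError("effect must exceed 1")
    rng = np.random.default_rng(cfg.seed)
    stages = ("control", "ko")
    design = SampleDesign.from_layout(list(stages), cfg.n_replicates)
    stage_index = np.array([stages.index(design.stage_of[s])
                            for s in design.samples])

    base_cfg = SyntheticConfig.from_dict(
        {**cfg.to_dict(), "n_stages": 2, "stage_labels": list(stages),
         "module_trajectories": [], "module_site_fractions": [],
         "planted_active": {}})
    protein_ids, site_meta, sequences = _base_structure(base_cfg, rng)

    n_sites = len(site_meta)
    n_down = int(round(frac_down * n_sites))
    down = np.zeros(n_sites, dtype=bool)
    down[:n_down] = True
    down = down[rng.permutation(n_sites)]

    mult = np.ones((n_sites, 2))
    mult[down, 1] = 1.0 / effect
    multipliers = mult[:, stage_index]

    protein_cells = _protein_cells(base_cfg, rng, design, stage_index)
    recs = _assemble_sites(base_cfg, design, site_meta, multipliers,
                           protein_cells, rng, sequences)
    proteins, _ = _emit_proteins(base_cfg, design, protein_ids,
                                 protein_cells, rng)
    sites = PhosphoSites(recs, design)

    expected = pd.DataFrame(mult / mult.mean(axis=1)[:, None],
                            index=site_meta["site_id"], columns=list(stages))
    truth = SyntheticTruth(
        site_module=pd.Series(0, index=site_meta["site_id"], name="module"),
        kinase_module={}, edges=pd.DataFrame(
            columns=["kinase", "protein_id", "residue", "position", "tier"]),
        expected_stage_means=expected,
        ko_label=pd.Series(np.where(down, "down", "null"),
                           index=site_meta["site_id"], name="ko_label"))
    return KOExperiment(proteins=proteins, sites=sites, truth=truth,
                        sequences=sequences)


def write_stage_experiment(exp: StageExperiment, outdir: str | Path,
                           config: SyntheticConfig | None = None) -> Path:
    """Emit the experiment as the TSV dialects the readers consume."""
    from . import quant_io  # deferred: quant_io imports core only

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    quant_io.write_quant_table(exp.proteins, outdir / "proteins.tsv")
    quant_io.write_site_table(exp.sites, outdir / "sites.tsv")
    quant_io.write_ksr_table(exp.ksr, outdir / "ksr.tsv")
    quant_io.write_design(exp.sites.design, outdir / "design.tsv")
    quant_io.write_fasta(exp.sequences, outdir / "proteins.fasta")
    pd.concat([exp.truth.site_module,
               exp.truth.expected_stage_means.add_prefix("expected_")],
              axis=1).to_csv(outdir / "truth_sites.tsv", sep="\t",
                             index_label="site_id")
    pd.DataFrame([(k, m, c) for k, (m, c) in exp.truth.kinase_module.items()],
                 columns=["kinase", "module", "planted_class"]
                 ).to_csv(outdir / "truth_kinases.tsv", sep="\t", index=False)
    if config is not None:
        (outdir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2))
    return outdir
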