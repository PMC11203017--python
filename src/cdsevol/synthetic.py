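"""Synthetic coding-sequence data with known ground truth.

Three generators cover every input the pipeline consumes:

* :func:`gen_cds_cohort` — CDS cohorts whose codon choice is driven by a
  third-base composition (tunable GC3) times an exponential preference for
  one designated codon per synonymous family (tunable selection strength).
  With selection strength 0 the cohort is the mutational-null regime in
  which ENC tracks the compositional expectation.
* :func:`gen_diverged_pair` — two descendants of an ancestor evolved
  independently under a continuous-time codon process with target dN/dS
  (omega), transition/transversion ratio kappa and a divergence scale t
  expressed as expected synonymous substitutions per synonymous site;
  substitutions are sampled event by event (Gillespie), changes to stop
  codons are forbidden, and realized synonymous/nonsynonymous counts are
  recorded as truth.
* :func:`gen_annotation_tables` — NR/Pfam/InterPro flag tables and GO maps
  with planted species-specific genes and planted enriched terms.  Default
  background annotation rates follow typical plant transcriptome annotation
  coverage (NR 0.848, Pfam 0.629, InterPro 0.703).

All randomness flows from ``SyntheticConfig.seed`` through a single
``numpy`` generator, so identical configs give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genetics import BASES, CODON_TO_AA, STOP_CODONS, SYN_FAMILIES, is_transition
from .seqio import CdsSet, CodingSequence
from .selection import count_sites

_AAS = sorted(SYN_FAMILIES)  # 20 amino acids
_STOPS = sorted(STOP_CODONS)


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 200
    len_codons: int = 300  # mean length; lengths are Poisson-distributed
    gc3_target: float = 0.5
    selection_strength: float = 0.0
    omega: float = 0.1
    divergence: float = 0.2
    ti_tv: float = 1.0
    third_base_mode: str = "gc"  # "gc" | "per_gene"
    dirichlet_alpha: float = 0.5
    n_specific: int = 10
    n_enriched_terms: int = 1
    enrichment_fold: float = 5.0
    n_go_terms: int = 40
    study_fraction: float = 0.1
    nr_rate: float = 0.848
    pfam_rate: float = 0.629
    interpro_rate: float = 0.703

    def validate(self) -> None:
        if not 0.0 <= self.gc3_target <= 1.0:
            raise ValueError("gc3_target must be in [0, 1]")
        if self.selection_strength < 0 or self.omega < 0 or self.divergence < 0:
            raise ValueError("selection_strength, omega and divergence must be >= 0")
        if self.ti_tv <= 0:
            raise ValueError("ti_tv must be positive")
        if self.third_base_mode not in ("gc", "per_gene"):
            raise ValueError(f"unknown third_base_mode {self.third_base_mode!r}")
        if self.n_specific > self.n_genes:
            raise ValueError("n_specific cannot exceed n_genes")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: designated preferred codon per amino acid (alphabetically first in family)
PREFERRED_CODON = {aa: codons[0] for aa, codons in SYN_FAMILIES.items()}


def _base_weights(config: SyntheticConfig, rng: np.random.Generator) -> dict[str, float]:
    """Third-base weight vector for one gene."""
    if config.third_base_mode == "per_gene":
        w = rng.dirichlet(np.full(4, config.dirichlet_alpha))
        return dict(zip(BASES, w))
    g = config.gc3_target
    return {"A": 1.0 - g, "C": g, "G": g, "T": 1.0 - g}


def _family_probs(
    weights: dict[str, float], s_sel: float
) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per-amino-acid codon sampling distribution."""
    out = {}
    for aa, codons in SYN_FAMILIES.items():
        w = np.array(
            [
                weights[c[2]] * (np.exp(s_sel) if c == PREFERRED_CODON[aa] else 1.0)
                for c in codons
            ]
        )
        total = w.sum()
        if total <= 0:  # all third-base weights zero for this family
            w = np.ones(len(codons))
            total = w.sum()
        out[aa] = (codons, w / total)
    return out


def gen_cds_cohort(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[CdsSet, pd.DataFrame]:
    """Generate a CDS cohort plus a per-gene truth table.

    Each gene starts with ATG, draws amino acids uniformly, picks codons with
    probability proportional to third-base weight x exp(s_sel * preferred),
    and ends with a stop codon (stripped again by validation).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sequences, rows = [], []
    for i in range(config.n_genes):
        length = max(10, int(rng.poisson(config.len_codons)))
        weights = _base_weights(config, rng)
        probs = _family_probs(weights, config.selection_strength)
        aa_seq = ["M"] + list(rng.choice(_AAS, size=length - 1))
        codons = [""] * length
        # draw per amino acid in bulk, then place in order
        positions: dict[str, list[int]] = {}
        for pos, aa in enumerate(aa_seq):
            positions.setdefault(aa, []).append(pos)
        for aa, pos_list in positions.items():
            fam, p = probs[aa]
            draws = rng.choice(len(fam), size=len(pos_list), p=p)
            for pos, d in zip(pos_list, draws):
                codons[pos] = fam[d]
        stop_w = np.array([weights[s[2]] for s in _STOPS])
        if stop_w.sum() <= 0:
            stop_w = np.ones(len(_STOPS))
        stop = _STOPS[rng.choice(len(_STOPS), p=stop_w / stop_w.sum())]
        gene_id = f"gene{i + 1:05d}"
        sequences.append(CodingSequence(id=gene_id, seq="".join(codons) + stop))
        rows.append(
            {
                "gene_id": gene_id,
                "len_codons": length,
                "regime": "null" if config.selection_strength == 0 else "selected",
                "selection_strength": config.selection_strength,
                "third_base_mode": config.third_base_mode,
                **{f"w_{b}": weights[b] for b in BASES},
            }
        )
    return CdsSet(species="synthetic", sequences=sequences), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# divergence simulation


@lru_cache(maxsize=None)
def _neighbours(codon: str) -> tuple[tuple[int, str, str, bool, bool], ...]:
    """(pos, new_base, new_codon, is_synonymous, is_transition) per non-stop change."""
    out = []
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            out.append(
                (pos, base, mutant, CODON_TO_AA[mutant] == aa,
                 is_transition(codon[pos], base))
            )
    return tuple(out)


def _change_rates(codon: str, omega: float, kappa: float) -> np.ndarray:
    return np.array(
        [
            (kappa if ti else 1.0) * (1.0 if syn else omega)
            for _, _, _, syn, ti in _neighbours(codon)
        ]
    )


def _evolve_branch(
    codons: list[str],
    duration: float,
    omega: float,
    kappa: float,
    rng: np.random.Generator,
) -> tuple[list[str], int, int]:
    """Gillespie simulation of one branch; returns (codons, n_syn, n_nonsyn)."""
    codons = list(codons)
    rates = np.array([_change_rates(c, omega, kappa).sum() for c in codons])
    total = rates.sum()
    n_syn = n_nonsyn = 0
    time = 0.0
    while total > 0:
        time += rng.exponential(1.0 / total)
        if time > duration:
            break
        idx = rng.choice(len(codons), p=rates / total)
        nbrs = _neighbours(codons[idx])
        r = _change_rates(codons[idx], omega, kappa)
        j = rng.choice(len(nbrs), p=r / r.sum())
        _, _, new_codon, syn, _ = nbrs[j]
        if syn:
            n_syn += 1
        else:
            n_nonsyn += 1
        codons[idx] = new_codon
        total -= rates[idx]
        rates[idx] = _change_rates(new_codon, omega, kappa).sum()
        total += rates[idx]
    return codons, n_syn, n_nonsyn


def gen_diverged_pair(
    ancestor: CodingSequence,
    omega: float,
    t: float,
    kappa: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[CodingSequence, CodingSequence, dict]:
    """Evolve two descendants of ``ancestor`` for t/2 each under target omega.

    ``t`` is the pair divergence in expected synonymous substitutions per
    synonymous (NG86) site.  Branch durations are calibrated from the
    ancestor's total synonymous flux.  Returns the descendants and a truth
    dict with realized substitution counts per branch.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    codons = [c for c in ancestor.codons() if c not in STOP_CODONS and "N" not in c]
    if not codons:
        raise ValueError("ancestor has no usable codons")
    s_sites = sum(count_sites(c)[0] for c in codons)
    syn_flux = sum(
        sum((kappa if ti else 1.0) for _, _, _, syn, ti in _neighbours(c) if syn)
        for c in codons
    )
    duration = t * s_sites / (2.0 * syn_flux) if syn_flux > 0 else 0.0

    truth = {"omega": omega, "t": t, "kappa": kappa, "s_sites_ancestor": s_sites}
    desc = []
    for branch in ("a", "b"):
        evolved, n_syn, n_nonsyn = _evolve_branch(codons, duration, omega, kappa, rng)
        desc.append(
            CodingSequence(id=f"{ancestor.id}_{branch}", seq="".join(evolved))
        )
        truth[f"syn_subs_{branch}"] = n_syn
        truth[f"nonsyn_subs_{branch}"] = n_nonsyn
    return desc[0], desc[1], truth


def gen_pair_cohort(
    config: SyntheticConfig, n_pairs: Optional[int] = None
) -> tuple[CdsSet, CdsSet, pd.DataFrame]:
    """Cohort of diverged pairs as two parallel species sets (focal/comparator)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pairs = n_pairs if n_pairs is not None else config.n_genes
    anc_cfg = dataclasses.replace(config, n_genes=n_pairs)
    ancestors, _ = gen_cds_cohort(anc_cfg, rng=rng)
    set_a, set_b, rows = [], [], []
    for anc in ancestors:
        a, b, truth = gen_diverged_pair(
            anc, config.omega, config.divergence, config.ti_tv, rng=rng
        )
        set_a.append(a)
        set_b.append(b)
        rows.append({"id_a": a.id, "id_b": b.id, **truth})
    return (
        CdsSet(species="focal", sequences=set_a),
        CdsSet(species="comparator", sequences=set_b),
        pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# annotation / GO tables


def gen_annotation_tables(
    config: SyntheticConfig, cds_set: CdsSet
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Annotation flags, GO map and truth with planted structure.

    Exactly ``n_specific`` genes satisfy the species-specific rule (domain
    evidence, no NR hit, no comparator orthogroup).  ``n_enriched_terms`` GO
    terms are enriched ``enrichment_fold``-fold in a designated study set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    ids = list(cds_set.ids)
    n = len(ids)
    if config.n_specific > n:
        raise ValueError("n_specific exceeds cohort size")
    specific = set(rng.choice(ids, size=config.n_specific, replace=False)) if n else set()

    rows = []
    for g in ids:
        if g in specific:
            nr, pfam = False, True
            ipr = bool(rng.random() < config.interpro_rate)
            og1 = og2 = ""
        else:
            nr = bool(rng.random() < config.nr_rate)
            pfam = bool(rng.random() < config.pfam_rate)
            ipr = bool(rng.random() < config.interpro_rate)
            og1 = f"OG1_{rng.integers(1, max(2, n // 2)):05d}" if rng.random() < 0.8 else ""
            og2 = f"OG2_{rng.integers(1, max(2, n // 2)):05d}" if rng.random() < 0.8 else ""
            # a background gene must never satisfy the specificity rule
            if (pfam or ipr) and not nr and not (og1 or og2):
                og1 = f"OG1_{rng.integers(1, max(2, n // 2)):05d}"
        rows.append(
            {
                "gene_id": g,
                "nr_hit": int(nr),
                "pfam_hit": int(pfam),
                "interpro_hit": int(ipr),
                "og_comparator1": og1,
                "og_comparator2": og2,
            }
        )
    annotations = pd.DataFrame(rows)

    n_study = max(1, int(round(config.study_fraction * n))) if n else 0
    study = sorted(rng.choice(ids, size=n_study, replace=False)) if n else []
    classes = ["BP", "CC", "MF"]
    go_rows = []
    planted_terms = []
    study_set = set(study)
    for ti in range(config.n_go_terms):
        term = f"GO:{ti + 1:07d}"
        go_class = classes[ti % 3]
        base = rng.uniform(0.02, 0.10)
        planted = ti < config.n_enriched_terms
        if planted:
            planted_terms.append(term)
        p_study = min(1.0, config.enrichment_fold * base) if planted else base
        for g in ids:
            p = p_study if g in study_set else base
            if rng.random() < p:
                go_rows.append(
                    {
                        "gene_id": g,
                        "go_id": term,
                        "go_class": go_class,
                        "go_name": f"synthetic term {ti + 1}",
                    }
                )
    go_map = pd.DataFrame(
        go_rows, columns=["gene_id", "go_id", "go_class", "go_name"]
    )
    truth = {
        "specific_genes": sorted(specific),
        "planted_terms": planted_terms,
        "study_genes": list(study),
    }
    return annotations, go_map, truth


# ---------------------------------------------------------------------------
# presets

PRESETS = ("null-usage", "biased-usage", "dnds-grid", "specificity", "enrichment")


def simulate_preset(preset: str, outdir: str | Path, seed: int = 0) -> dict:
    """Write the input files of a named scenario; returns the manifest dict.

    Scenario sizes are chosen for fast, fully deterministic end-to-end runs;
    the statistically calibrated regimes used by the validation suite call
    the generators directly with their own configs.
    """
    from .seqio import write_fasta  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"preset": preset, "seed": seed, "files": {}}

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = path.name

    if preset == "null-usage":
        cfg = SyntheticConfig(seed=seed, n_genes=200, len_codons=300)
        cohort, truth = gen_cds_cohort(cfg)
        write_fasta(cohort, outdir / "focal.fasta")
        truth.to_csv(outdir / "truth_cohort.tsv", sep="\t", index=False)
        record("focal_fasta", outdir / "focal.fasta")
        manifest["config"] = cfg.to_dict()
    elif preset == "biased-usage":
        cfg = SyntheticConfig(
            seed=seed, n_genes=200, len_codons=300,
            selection_strength=2.0, third_base_mode="per_gene",
        )
        cohort, truth = gen_cds_cohort(cfg)
        write_fasta(cohort, outdir / "focal.fasta")
        truth.to_csv(outdir / "truth_cohort.tsv", sep="\t", index=False)
        record("focal_fasta", outdir / "focal.fasta")
        manifest["config"] = cfg.to_dict()
    elif preset == "dnds-grid":
        focal_all, comp_all, truths = [], [], []
        for i, omega in enumerate((0.1, 0.5, 1.0, 2.0)):
            # low divergence keeps even the omega > 1 pairs above the
            # coverage/identity filters, so every class is visible end-to-end
            cfg = SyntheticConfig(
                seed=seed + i, n_genes=6, len_codons=200,
                omega=omega, divergence=0.05, n_specific=0,
            )
            fa, cb, truth = gen_pair_cohort(cfg)
            # prefix ids so the four sub-grids do not collide
            for s in fa:
                s.id = f"w{omega}_{s.id}"
            for s in cb:
                s.id = f"w{omega}_{s.id}"
            truth["id_a"] = "w" + str(omega) + "_" + truth["id_a"]
            truth["id_b"] = "w" + str(omega) + "_" + truth["id_b"]
            focal_all.extend(fa.sequences)
            comp_all.extend(cb.sequences)
            truths.append(truth)
        write_fasta(CdsSet("focal", focal_all), outdir / "focal.fasta")
        write_fasta(CdsSet("comparator", comp_all), outdir / "comparator.fasta")
        pd.concat(truths, ignore_index=True).to_csv(
            outdir / "truth_pairs.tsv", sep="\t", index=False
        )
        record("focal_fasta", outdir / "focal.fasta")
        record("comparator_fasta", outdir / "comparator.fasta")
        manifest["config"] = {"omegas": [0.1, 0.5, 1.0, 2.0], "seed": seed}
    elif preset == "specificity":
        cfg = SyntheticConfig(seed=seed, n_genes=150, len_codons=100, n_specific=10)
        cohort, _ = gen_cds_cohort(cfg)
        annotations, go_map, truth = gen_annotation_tables(cfg, cohort)
        write_fasta(cohort, outdir / "focal.fasta")
        annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        go_map.to_csv(outdir / "go_map.tsv", sep="\t", index=False)
        (outdir / "truth_tables.json").write_text(json.dumps(truth, indent=1))
        record("focal_fasta", outdir / "focal.fasta")
        record("annotations", outdir / "annotations.tsv")
        record("go_map", outdir / "go_map.tsv")
        manifest["config"] = cfg.to_dict()
    elif preset == "enrichment":
        cfg = SyntheticConfig(
            seed=seed, n_genes=300, len_codons=60,
            n_enriched_terms=1, enrichment_fold=5.0,
        )
        cohort, _ = gen_cds_cohort(cfg)
        annotations, go_map, truth = gen_annotation_tables(cfg, cohort)
        write_fasta(cohort, outdir / "focal.fasta")
        annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        go_map.to_csv(outdir / "go_map.tsv", sep="\t", index=False)
        (outdir / "truth_tables.json").write_text(json.dumps(truth, indent=1))
        record("focal_fasta", outdir / "focal.fasta")
        record("annotations", outdir / "annotations.tsv")
        record("go_map", outdir / "go_map.tsv")
        manifest["config"] = cfg.to_dict()
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
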