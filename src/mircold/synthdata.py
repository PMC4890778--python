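"""Synthetic sRNA-seq study generator with planted ground truth.

Emulates the four-library design of a reproductive-tissue cold-stress
experiment — anther/ovary x control/stress (library ids HCA, HSA, HCO,
HSO) — producing every input the pipeline consumes:

* a mature-miRNA catalog (miRBase-style headers) containing the planted
  conserved matures verbatim;
* a contaminant ncRNA set (rRNA/tRNA/snoRNA stand-ins) guaranteed not to
  match any planted mature within 2 mismatches on either strand;
* transcript contigs with planted novel-miRNA precursors (hairpins that
  provably pass the annotation criteria — each constructed precursor is
  validated with the hairpin module before acceptance) and planted
  perfect-complement target sites;
* adapter-ligated FASTQ libraries with Poisson per-miRNA counts, known
  per-contrast fold changes, contaminant reads and i.i.d. substitution
  errors;
* a stem-loop RT-qPCR Ct table with planted relative-expression ratios.

Everything is driven by a single seed through named substreams, so
identical parameters give byte-identical output files.

The count model is Poisson around the expected per-library means: the
emulated design has one library per condition, so no dispersion is
estimable and Poisson is the model under which the downstream exact test
is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import hairpin
from ._seq import DNA_BASES, hamming, random_seq, revcomp

__all__ = [
    "SynthParams",
    "PlantedMiRNA",
    "GroundTruth",
    "References",
    "build_references",
    "write_references",
    "simulate_libraries",
    "simulate_ct_table",
]

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_LIBRARIES = [
    ("HCA", "anther", "control"),
    ("HSA", "anther", "stress"),
    ("HCO", "ovary", "control"),
    ("HSO", "ovary", "stress"),
]

# family names cycled through when naming planted conserved matures
_FAMILY_POOL = [156, 159, 160, 162, 166, 168, 171, 319, 394, 398,
                403, 477, 482, 1511, 6285, 7122, 8123, 172, 164, 2111]

_CONTRAST_TISSUES = {"anther": ("HSA", "HCA"), "ovary": ("HSO", "HCO")}


@dataclass
class SynthParams:
    """Generator parameters; defaults define the standard study conditions."""

    seed: int = 0
    n_conserved: int = 20
    n_novel: int = 10
    n_contigs: int = 30
    contig_len: int = 2000
    adapter: str = DEFAULT_ADAPTER
    read_len: int = 51
    error_rate: float = 0.005
    depth: int = 100_000
    contaminant_frac: float = 0.2
    n_contaminants: int = 8
    libraries: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(DEFAULT_LIBRARIES))
    # planted-miRNA name -> {contrast: true log2 ratio}; None = default plan
    fold_changes: dict[str, dict[str, float]] | None = None

    def validate(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must lie in [0, 0.1)")
        if not self.adapter or any(c not in DNA_BASES for c in self.adapter):
            raise ValueError("adapter must be non-empty over A/C/G/T")
        if not (0 <= self.contaminant_frac < 1):
            raise ValueError("contaminant_frac must lie in [0, 1)")
        if self.fold_changes:
            for per in self.fold_changes.values():
                if any(not math.isfinite(v) for v in per.values()):
                    raise ValueError("fold changes must be finite")


@dataclass
class PlantedMiRNA:
    name: str
    mature: str
    cls: str               # conserved | novel
    arm: str               # 5p | 3p
    contig_id: str | None = None   # novel only
    precursor_start: int | None = None
    precursor_end: int | None = None
    mature_start: int | None = None
    mature_end: int | None = None


@dataclass
class GroundTruth:
    """Manifest binding planted miRNAs, abundances and expected calls."""

    planted: list[PlantedMiRNA]
    expected_counts: dict[str, dict[str, float]]   # name -> library -> mean
    fold_changes: dict[str, dict[str, float]]      # name -> contrast -> log2FC
    contaminant_names: list[str]
    true_calls: dict[str, dict[str, str]]          # name -> contrast -> up/down/ns
    target_sites: dict[str, tuple[str, int]] = field(default_factory=dict)
    planted_rq: dict[str, dict[str, float]] = field(default_factory=dict)
    qpcr_pairing: dict[str, list[str]] = field(default_factory=dict)

    def by_class(self, cls: str) -> list[PlantedMiRNA]:
        return [p for p in self.planted if p.cls == cls]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [vars(p) for p in self.planted],
            "expected_counts": self.expected_counts,
            "fold_changes": self.fold_changes,
            "contaminant_names": self.contaminant_names,
            "true_calls": self.true_calls,
            "target_sites": {k: list(v) for k, v in self.target_sites.items()},
            "planted_rq": self.planted_rq,
            "qpcr_pairing": self.qpcr_pairing,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class References:
    catalog: dict[str, str]        # name -> mature (DNA)
    contaminants: dict[str, str]
    contigs: dict[str, str]


def _substream(seed: int, channel: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, channel]))


# ---------------------------------------------------------------------------
# reference construction


def _mature_name(i: int, cls: str, arm: str) -> str:
    fam = _FAMILY_POOL[i % len(_FAMILY_POOL)]
    letter = chr(ord("a") + (i // len(_FAMILY_POOL)) % 26)
    if cls == "conserved":
        return f"pdu-miR{fam}{letter}-{arm}"
    return f"pdu-miRn{i + 1:02d}-{arm}"


def _distinct(seq: str, others: Sequence[str], min_mm: int = 3) -> bool:
    """True when seq is Hamming >= min_mm from every same-length other
    (over best end-to-end overlap for near-equal lengths)."""
    for o in others:
        short, long_ = (seq, o) if len(seq) <= len(o) else (o, seq)
        if len(long_) - len(short) > 2:
            continue
        for off in range(len(long_) - len(short) + 1):
            if hamming(short, long_[off : off + len(short)]) < min_mm:
                return False
    return True


def _make_matures(rng: np.random.Generator, n: int, existing: list[str],
                  forbid: str | None = None) -> list[str]:
    """Random mature sequences, mutually >= 3 mismatches apart.

    ``forbid`` excludes matures containing the given motif (the adapter's
    seed prefix — an internal occurrence would derail adapter trimming).
    """
    out: list[str] = []
    lengths = [21, 21, 21, 20, 22, 21, 19, 21, 20, 21]  # 21 nt most abundant
    while len(out) < n:
        L = lengths[len(out) % len(lengths)]
        m = random_seq(rng, L, gc=0.5)
        if forbid and forbid in m:
            continue
        if 35 <= 100 * (m.count("G") + m.count("C")) / L <= 65 and \
                _distinct(m, existing + out):
            out.append(m)
    return out


def _engineer_precursor(rng: np.random.Generator, mature: str, arm: str
                        ) -> tuple[str, int]:
    """arm + loop + near-reverse-complement arm; returns (precursor, mature offset).

    The star arm carries at most 2 engineered mismatches and the loop is
    6-12 nt, so the construct folds into a criteria-passing hairpin under
    any reasonable thermodynamic backend.
    """
    loop_len = int(rng.integers(6, 13))
    loop = random_seq(rng, loop_len, gc=0.2)  # AU-rich loop resists pairing
    star = list(revcomp(mature))
    n_mm = int(rng.integers(0, 3))
    # keep engineered mismatches away from the star ends so the closing
    # stem pairs cleanly
    if n_mm and len(star) > 8:
        pos = rng.choice(np.arange(3, len(star) - 3), size=n_mm, replace=False)
        for p in pos:
            choices = [b for b in DNA_BASES if b != star[p]]
            star[p] = choices[int(rng.integers(0, 3))]
    star_seq = "".join(star)
    if arm == "5p":
        return mature + loop + star_seq, 0
    return star_seq + loop + mature, len(star_seq) + loop_len


def _passes_hairpin(precursor: str, offset: int, mature: str) -> bool:
    cand = hairpin.PrecursorCandidate(
        contig_id="synthetic", window_start=0, window_end=len(precursor),
        strand="+", seq=precursor, mature_offset=offset, tag_seq=mature)
    ev = hairpin.evaluate_hairpin(cand, hairpin.fold(precursor))
    return ev.passed


def _default_fold_changes(names_conserved: list[str], names_novel: list[str]
                          ) -> dict[str, dict[str, float]]:
    """Default experimental plan: strong induction/repression for a subset.

    Six conserved and two novel miRNAs respond to cold (|log2FC| in
    {2, 2.5, 3}, mixed signs); each responder responds in exactly one
    tissue, and each tissue carries both up- and down-regulation so the
    expected library depths can be balanced. The rest are flat.
    """
    plan: dict[str, dict[str, float]] = {n: {"anther": 0.0, "ovary": 0.0}
                                         for n in names_conserved + names_novel}
    effects = [
        (0, "anther", -2.0),
        (1, "anther", 2.5),
        (2, "ovary", 3.0),
        (3, "ovary", -2.5),
        (4, "anther", 3.0),
        (5, "ovary", -2.0),
    ]
    for idx, tissue, lfc in effects:
        if idx < len(names_conserved):
            plan[names_conserved[idx]][tissue] = lfc
    if names_novel:
        plan[names_novel[0]]["anther"] = 2.0
    if len(names_novel) > 1:
        plan[names_novel[1]]["ovary"] = -2.0
    return plan


def _balance_weights(weights: np.ndarray, lfc_rows: list[dict[str, float]],
                     tissues: Sequence[str], sweeps: int = 8) -> np.ndarray:
    """Rescale down-regulated entities so stress and control library depths
    match in expectation: per tissue, sum_i w_i * 2^lfc_i = sum_i w_i.

    One sweep is exact when responders are tissue-disjoint (the default
    plan); overlapping custom plans converge over a few sweeps.
    """
    w = weights.astype(float).copy()
    for _ in range(sweeps):
        moved = 0.0
        for tissue in tissues:
            lfc = np.array([row.get(tissue, 0.0) for row in lfc_rows])
            up = lfc > 0
            down = lfc < 0
            surplus = float(np.sum(w[up] * (2.0 ** lfc[up] - 1.0)))
            deficit = float(np.sum(w[down] * (1.0 - 2.0 ** lfc[down])))
            if surplus > 0 and deficit > 0:
                scale = surplus / deficit
                w[down] *= scale
                moved = max(moved, abs(math.log(scale)))
        if moved < 1e-12:
            break
    return w / w.sum()


def build_references(params: SynthParams) -> tuple[References, GroundTruth]:
    """Construct catalog, contaminants and contigs with planted truth.

    Novel precursors are validated against the hairpin module's criteria
    before acceptance; contaminants are exhaustively checked to share no
    <=2-mismatch window with any planted mature on either strand.
    """
    params.validate()
    rng_cat = _substream(params.seed, 1)
    rng_nov = _substream(params.seed, 2)
    rng_cont = _substream(params.seed, 3)
    rng_ctg = _substream(params.seed, 4)
    rng_ab = _substream(params.seed, 5)

    forbid = params.adapter[:6]
    conserved_seqs = _make_matures(rng_cat, params.n_conserved, [], forbid)
    novel_seqs = _make_matures(rng_nov, params.n_novel, conserved_seqs, forbid)

    planted: list[PlantedMiRNA] = []
    catalog: dict[str, str] = {}
    for i, m in enumerate(conserved_seqs):
        arm = "5p" if i % 2 == 0 else "3p"
        name = _mature_name(i, "conserved", arm)
        catalog[name] = m
        planted.append(PlantedMiRNA(name=name, mature=m, cls="conserved", arm=arm))

    # contigs on a fixed non-overlapping slot grid; each novel precursor is
    # engineered, planted, then validated IN CONTEXT (the excised +/-150
    # window must pass the hairpin criteria) before being accepted —
    # incidental pairing with flanking sequence can otherwise spoil a
    # construct that folds cleanly in isolation
    slot = 600
    margin = 200
    if params.n_novel and params.contig_len < 80 + 2 * margin:
        raise ValueError(
            f"contig_len {params.contig_len} too short to host a precursor "
            f"with flanking sequence")
    slots_per_contig = max(1, (params.contig_len - 2 * margin) // slot)
    if params.n_novel > params.n_contigs * slots_per_contig:
        raise ValueError("not enough contig space for the requested novel miRNAs")

    contigs = {f"contig{i + 1:03d}": random_seq(rng_ctg, params.contig_len, gc=0.45)
               for i in range(params.n_contigs)}
    contig_ids = list(contigs)
    for i in range(params.n_novel):
        arm = "3p" if i % 3 != 0 else "5p"   # ~2/3 on the 3' arm
        cid = contig_ids[i % params.n_contigs]
        pos = margin + (i // params.n_contigs) * slot
        mature = novel_seqs[i]
        for _attempt in range(60):
            prec, off = _engineer_precursor(rng_nov, mature, arm)
            if not _passes_hairpin(prec, off, mature):
                mature = _make_matures(rng_nov, 1, conserved_seqs + novel_seqs, forbid)[0]
                continue
            planted_contig = contigs[cid][:pos] + prec + contigs[cid][pos + len(prec):]
            hit = hairpin.TagHit(mature, cid, pos + off, pos + off + len(mature), "+")
            cand = hairpin.extract_precursor(hit, {**contigs, cid: planted_contig})
            if hairpin.evaluate_hairpin(cand, hairpin.fold(cand.seq)).passed:
                break
            mature = _make_matures(rng_nov, 1, conserved_seqs + novel_seqs, forbid)[0]
        else:
            raise RuntimeError("failed to engineer a passing precursor in context")
        novel_seqs[i] = mature
        contigs[cid] = planted_contig
        name = _mature_name(i, "novel", arm)
        p = PlantedMiRNA(
            name=name, mature=mature, cls="novel", arm=arm, contig_id=cid,
            precursor_start=pos, precursor_end=pos + len(prec),
            mature_start=pos + off, mature_end=pos + off + len(mature))
        planted.append(p)

    # planted perfect-complement target sites for the first conserved matures
    target_sites: dict[str, tuple[str, int]] = {}
    n_targets = min(4, params.n_conserved, params.n_contigs)
    for i in range(n_targets):
        p = planted[i]
        cid = contig_ids[-(i + 1)]
        pos = params.contig_len - margin - 60 * (i + 1)
        site = revcomp(p.mature)
        c = contigs[cid]
        contigs[cid] = c[:pos] + site + c[pos + len(site):]
        target_sites[p.name] = (cid, pos)

    # contaminants with exhaustive no-leakage check against planted matures
    matures = [p.mature for p in planted]
    contaminants: dict[str, str] = {}
    kinds = ["rRNA", "tRNA", "snoRNA", "chloroplast"]
    i = 0
    while len(contaminants) < params.n_contaminants:
        L = int(rng_cont.integers(120, 400))
        seq = random_seq(rng_cont, L, gc=0.55)
        leaky = any(
            min(hamming(m, s[j:j + len(m)])
                for s in (seq, revcomp(seq))
                for j in range(len(s) - len(m) + 1)) <= 2
            for m in matures if len(m) <= L
        )
        if leaky:
            continue
        name = f"{kinds[i % len(kinds)]}_{i + 1:02d}"
        contaminants[name] = seq
        i += 1

    # abundances and fold changes
    if params.fold_changes is not None:
        fold_changes = {n: dict(per) for n, per in params.fold_changes.items()}
        for p in planted:
            fold_changes.setdefault(p.name, {"anther": 0.0, "ovary": 0.0})
    else:
        fold_changes = _default_fold_changes(
            [p.name for p in planted if p.cls == "conserved"],
            [p.name for p in planted if p.cls == "novel"])

    mirna_reads = params.depth * (1.0 - params.contaminant_frac)
    weights = rng_ab.lognormal(mean=0.0, sigma=0.8, size=len(planted))
    tissues = sorted({tissue for _, tissue, _ in params.libraries})
    weights = _balance_weights(
        weights, [fold_changes.get(p.name, {}) for p in planted], tissues)
    expected: dict[str, dict[str, float]] = {}
    for p, w in zip(planted, weights):
        base = w * mirna_reads
        per_lib: dict[str, float] = {}
        for lib_id, tissue, condition in params.libraries:
            lfc = fold_changes.get(p.name, {}).get(tissue, 0.0)
            per_lib[lib_id] = base * (2.0 ** lfc if condition == "stress" else 1.0)
        expected[p.name] = per_lib

    true_calls = {
        name: {contrast: ("up" if lfc > 0.5 else "down" if lfc < -0.5 else "ns")
               for contrast, lfc in per.items()}
        for name, per in fold_changes.items()
    }

    truth = GroundTruth(
        planted=planted, expected_counts=expected, fold_changes=fold_changes,
        contaminant_names=list(contaminants), true_calls=true_calls,
        target_sites=target_sites,
    )
    _plan_qpcr(truth)
    refs = References(catalog=catalog, contaminants=contaminants, contigs=contigs)
    return refs, truth


def _plan_qpcr(truth: GroundTruth) -> None:
    """Planted qPCR relative quantities and miRNA->target pairing.

    Samples are genotype x tissue x temperature (10 C is the calibrator);
    responding miRNAs follow their sequencing fold change in the tolerant
    genotype at 0 C (stronger at -2 C), with one miRNA planted at the
    landmark 8.6-fold ovary induction; each paired target moves exactly
    opposite its miRNA.
    """
    responders = [n for n, per in truth.fold_changes.items()
                  if any(abs(v) > 0.5 for v in per.values())][:6]
    rq: dict[str, dict[str, float]] = {}
    pairing: dict[str, list[str]] = {}
    for i, name in enumerate(responders):
        per_sample: dict[str, float] = {}
        for genotype in ("H", "Sh12"):
            for tissue in ("anther", "ovary"):
                lfc = truth.fold_changes[name].get(tissue, 0.0)
                if genotype == "Sh12":
                    lfc = -lfc  # sensitive genotype responds oppositely
                per_sample[f"{genotype}_{tissue}_10C"] = 1.0
                per_sample[f"{genotype}_{tissue}_0C"] = 2.0 ** lfc
                per_sample[f"{genotype}_{tissue}_-2C"] = 2.0 ** (1.2 * lfc)
        rq[name] = per_sample
        target = f"target_{name}"
        pairing[name] = [target]
        rq[target] = {s: 1.0 / v for s, v in per_sample.items()}
    if responders:
        # landmark induction: 8.6-fold in the tolerant genotype's ovary at 0 C
        landmark = responders[0]
        rq[landmark]["H_ovary_0C"] = 8.6
        rq[f"target_{landmark}"]["H_ovary_0C"] = 1.0 / 8.6
    truth.planted_rq = rq
    truth.qpcr_pairing = pairing


def write_references(refs: References, outdir: str | Path) -> dict[str, Path]:
    """Write catalog/contaminant/contig FASTA files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stem, seqs in (("catalog", refs.catalog),
                       ("contaminants", refs.contaminants),
                       ("contigs", refs.contigs)):
        path = outdir / f"{stem}.fasta"
        with open(path, "w") as fh:
            for name in seqs:
                fh.write(f">{name}\n{seqs[name]}\n")
        paths[stem] = path
    return paths


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(reads: list[str], rng: np.random.Generator, rate: float) -> list[str]:
    """i.i.d. substitution errors at ``rate`` per base (vectorized)."""
    if rate <= 0 or not reads:
        return reads
    out: list[str] = []
    joined = "".join(reads)
    arr = np.frombuffer(joined.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    n_err = int(mask.sum())
    if n_err:
        # substitute with one of the three other bases
        base_idx = {65: 0, 67: 1, 71: 2, 84: 3}
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        cur = np.array([base_idx.get(b, 0) for b in arr[mask]])
        shift = rng.integers(1, 4, size=n_err)
        arr[mask] = bases[(cur + shift) % 4]
    mutated = arr.tobytes().decode()
    pos = 0
    for r in reads:
        out.append(mutated[pos : pos + len(r)])
        pos += len(r)
    return out


def simulate_libraries(truth: GroundTruth, refs: References, params: SynthParams,
                       outdir: str | Path) -> dict:
    """Write four FASTQ libraries plus a realized-count manifest.

    Each read is a planted mature (or a contaminant fragment) with the 3'
    adapter appended, truncated to ``read_len``, then subjected to
    substitution errors. Per-miRNA counts are Poisson around the expected
    means; contaminant read totals are Poisson around
    depth * contaminant_frac. The manifest records realized source counts
    per library (before sequencing error).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"libraries": {}, "params": {"depth": params.depth,
                                                  "error_rate": params.error_rate}}
    names = [p.name for p in truth.planted]
    mature_by_name = {p.name: p.mature for p in truth.planted}
    cont_names = list(refs.contaminants)

    for lib_idx, (lib_id, tissue, condition) in enumerate(params.libraries):
        rng = _substream(params.seed, 100 + lib_idx)
        counts = {n: int(rng.poisson(truth.expected_counts[n][lib_id])) for n in names}
        n_cont = int(rng.poisson(params.depth * params.contaminant_frac)) \
            if params.contaminant_frac > 0 and cont_names else 0

        sources: list[str] = []
        for n in names:
            sources.extend([mature_by_name[n]] * counts[n])
        cont_realized = 0
        for _ in range(n_cont):
            cname = cont_names[int(rng.integers(0, len(cont_names)))]
            cseq = refs.contaminants[cname]
            L = int(rng.integers(18, 25))
            if len(cseq) < L:
                continue
            start = int(rng.integers(0, len(cseq) - L + 1))
            sources.append(cseq[start : start + L])
            cont_realized += 1

        order = rng.permutation(len(sources))
        reads = [(sources[i] + params.adapter)[: params.read_len] for i in order]
        reads = _apply_errors(reads, rng, params.error_rate)

        path = outdir / f"{lib_id}.fastq"
        with open(path, "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f"@{lib_id}_{i + 1}\n{r}\n+\n{'H' * len(r)}\n")

        manifest["libraries"][lib_id] = {
            "tissue": tissue, "condition": condition, "path": str(path),
            "total_reads": len(reads), "contaminant_reads": cont_realized,
            "mirna_counts": counts,
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# qPCR table simulation


def simulate_ct_table(truth: GroundTruth, params: SynthParams,
                      noise_sd: float = 0.15, n_technical: int = 3,
                      path: str | Path | None = None):
    """Simulate a stem-loop RT-qPCR Ct table from the planted RQ map.

    Ct(gene, sample) = baseline(gene) - log2(expression) + N(0, noise_sd)
    per technical replicate; reference genes (18S for miRNAs, PduAct1 for
    targets) are condition-independent. With ``noise_sd`` 0 the qPCR
    module recovers every planted ratio exactly.
    """
    import pandas as pd

    rng = _substream(params.seed, 200)
    rows = []
    genes = list(truth.planted_rq)
    references = {"18S": 12.0, "PduAct1": 19.0}
    baselines = {g: 22.0 + 1.5 * (i % 5) for i, g in enumerate(genes)}
    samples = sorted({s for per in truth.planted_rq.values() for s in per})
    for sample in samples:
        for gene in genes:
            expr = truth.planted_rq[gene].get(sample, 1.0)
            base_ct = baselines[gene] - math.log2(expr)
            for rep in range(1, n_technical + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append({"sample": sample, "gene": gene,
                             "replicate": rep, "ct": base_ct + noise})
        for ref_gene, ref_ct in references.items():
            for rep in range(1, n_technical + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append({"sample": sample, "gene": ref_gene,
                             "replicate": rep, "ct": ref_ct + noise})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
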