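"""Synthetic MPRA study generator with known ground truth.

Emulates the structure of a reporter-assay experiment on 150 bp
allele-pair elements: a designed library (variant ref/alt pairs,
constitutive positive controls, composition-preserving scrambled
negatives), random 20 bp barcode assignments, overdispersed DNA/RNA
barcode counts per replicate and condition, and the side-annotations
(repeat track, gene models, chromatin loops, position weight matrices,
regional expression and association statistics) the downstream stages
consume.  Every planted effect is recorded in a truth table so recovery
can be measured.

The count model is hierarchical: DNA barcode counts are negative
binomial with variance ``mean + dispersion * mean**2``; the RNA mean for
a barcode is its *realized* DNA count scaled by ``2**eta`` where ``eta``
collects the planted activity, allelic and condition-interaction
effects.  Each replicate draws its DNA library once and shares it across
conditions, mirroring the fact that the plasmid pool does not depend on
the stimulation a well later receives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("vehicle", "stim")
A_BOX = "TGGCTCACGCC"
B_BOX = "GTTCGAGAC"
_BASES = np.array(list("ACGT"))

# variant base sits at this 0-based offset of the 150-mer
VARIANT_OFFSET = 75
ELEMENT_LEN = 150


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic experiment.

    Sample sizes mirror the emulated study design: ~113 barcodes per
    variant before transfection (split across the two alleles), 16
    replicates per condition.  Count-model parameters (``dna_mean``,
    ``nb_dispersion``, depth spread) are free parameters of the
    generator; defaults are chosen to resemble a well-covered MPRA
    library and are documented as such.
    """

    n_variants: int = 200
    frac_active: float = 0.10
    frac_emvar: float = 0.10
    frac_interaction: float = 0.05
    n_negative_controls: int = 50
    n_positive_controls: int = 4
    barcodes_per_variant_mean: float = 113.0
    n_replicates_per_condition: int = 16
    dna_mean: float = 60.0
    nb_dispersion: float = 0.1
    depth_log2_sd: float = 0.25
    outlier_barcode_rate: float = 0.01
    outlier_factor: float = 8.0
    active_log2_alpha: float = 2.0
    allelic_lfc: float = 1.0
    interaction_beta: float = 1.0
    positive_log2_alpha: float = 3.0
    frac_alu: float = 0.3
    a_box_offset: int = 6
    b_box_offset: int = 90
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("frac_active", "frac_emvar", "frac_interaction", "frac_alu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.dna_mean <= 0:
            raise ValueError("dna_mean must be > 0")
        if self.n_variants == 0:
            raise ValueError("empty library: n_variants must be >= 1")
        if self.frac_emvar > self.frac_active:
            raise ValueError("emVar variants are planted among active variants")
        if self.frac_interaction > self.frac_emvar:
            raise ValueError("interaction variants are planted among emVars")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _rnegbin(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial draws parameterized by (mean, dispersion alpha).

    Variance is mean + alpha * mean**2; alpha -> 0 recovers Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size, p)


def generate_library(config: SimulationConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the designed element library and its truth table.

    Returns ``(library, truth)``.  ``library`` has one row per element
    (ref and alt allele of each variant, positive controls, scrambled
    negatives); ``truth`` records the planted log2 activity, allelic
    log-fold-change and condition-interaction coefficient per element.

    Active variants are the first ``round(frac_active * n_variants)``
    variants after a seeded shuffle; emVar variants are a subset of the
    active ones and interaction variants a subset of the emVars, so the
    downstream gating rules (allelic tests require activity; interaction
    tests require an emVar) are satisfiable by construction.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    n_var = config.n_variants
    order = rng.permutation(n_var)
    n_active = int(round(config.frac_active * n_var))
    n_emvar = int(round(config.frac_emvar * n_var))
    n_inter = int(round(config.frac_interaction * n_var))
    active_set = set(order[:n_active])
    emvar_set = set(order[:n_emvar])
    inter_set = set(order[:n_inter])

    n_alu = int(round(config.frac_alu * n_var))
    alu_set = set(order[-n_alu:]) if n_alu else set()

    lib_rows, truth_rows = [], []
    gwas_ref_seqs = []

    for i in range(n_var):
        variant_id = f"var{i:05d}"
        locus_id = f"locus{i // 5:04d}"
        category = "caqtl" if i % 10 == 0 else "gwas"
        chrom = f"chr{(i % 4) + 1}"
        start = 100_000 + 10_000 * i  # 0-based element start
        seq = list(_random_seq(rng, ELEMENT_LEN))
        alu_mode = None
        if i in alu_set:
            alu_mode = ("A", "B", "AB")[i % 3]
            if "A" in alu_mode:
                seq[config.a_box_offset:config.a_box_offset + len(A_BOX)] = A_BOX
            if "B" in alu_mode:
                seq[config.b_box_offset:config.b_box_offset + len(B_BOX)] = B_BOX
        ref_seq = "".join(seq)
        ref_base = ref_seq[VARIANT_OFFSET]
        alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        alt_seq = ref_seq[:VARIANT_OFFSET] + alt_base + ref_seq[VARIANT_OFFSET + 1:]
        if category == "gwas":
            gwas_ref_seqs.append(ref_seq)

        log2_alpha = config.active_log2_alpha if i in active_set else 0.0
        lfc = config.allelic_lfc if i in emvar_set else 0.0
        beta = config.interaction_beta if i in inter_set else 0.0

        for allele, s in (("ref", ref_seq), ("alt", alt_seq)):
            eid = f"{variant_id}_{allele}"
            lib_rows.append(dict(
                element_id=eid, variant_id=variant_id, allele=allele,
                category=category, chrom=chrom, start=start, end=start + ELEMENT_LEN,
                variant_pos=start + VARIANT_OFFSET + 1, strand="+",
                locus_id=locus_id, alu_mode=alu_mode or "", sequence=s,
            ))
            truth_rows.append(dict(
                element_id=eid, variant_id=variant_id,
                true_log2_alpha=log2_alpha,
                true_allelic_lfc=lfc, true_interaction_beta=beta,
                is_active=i in active_set, is_emvar=i in emvar_set,
                is_interaction=i in inter_set,
            ))

    for j in range(config.n_positive_controls):
        eid = f"pos{j:03d}"
        start = 50_000 + 1_000 * j
        lib_rows.append(dict(
            element_id=eid, variant_id="", allele="na",
            category="positive_control", chrom="chrX", start=start,
            end=start + ELEMENT_LEN, variant_pos=0, strand="+",
            locus_id=f"pos_locus{j}", alu_mode="",
            sequence=_random_seq(rng, ELEMENT_LEN),
        ))
        truth_rows.append(dict(
            element_id=eid, variant_id="",
            true_log2_alpha=config.positive_log2_alpha,
            true_allelic_lfc=0.0, true_interaction_beta=0.0,
            is_active=True, is_emvar=False, is_interaction=False,
        ))

    for j in range(config.n_negative_controls):
        # composition-preserving Fisher-Yates shuffle of a designed sequence
        src = gwas_ref_seqs[j % len(gwas_ref_seqs)]
        scrambled = "".join(rng.permutation(list(src)))
        eid = f"neg{j:03d}"
        start = 10_000 + 1_000 * j
        lib_rows.append(dict(
            element_id=eid, variant_id="", allele="na",
            category="negative_control", chrom="chrY", start=start,
            end=start + ELEMENT_LEN, variant_pos=0, strand="+",
            locus_id=f"neg_locus{j}", alu_mode="",
            sequence=scrambled,
        ))
        truth_rows.append(dict(
            element_id=eid, variant_id="", true_log2_alpha=0.0,
            true_allelic_lfc=0.0, true_interaction_beta=0.0,
            is_active=False, is_emvar=False, is_interaction=False,
        ))

    return pd.DataFrame(lib_rows), pd.DataFrame(truth_rows)


def assign_barcodes(library: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw barcode assignments: per element, Poisson-many unique 20-mers.

    The per-element mean is half the per-variant mean since each variant
    contributes two allele elements.
    """
    mean_per_element = max(config.barcodes_per_variant_mean / 2.0, 1.0)
    n_bc = np.maximum(rng.poisson(mean_per_element, size=len(library)), 1)
    total = int(n_bc.sum())
    codes = rng.integers(0, 4, size=(total, 20))
    barcodes = ["".join(b) for b in _BASES[codes]]
    # regenerate any collisions (vanishingly rare at 4^20)
    seen: set[str] = set()
    for k, bc in enumerate(barcodes):
        while bc in seen:
            bc = _random_seq(rng, 20)
        seen.add(bc)
        barcodes[k] = bc
    return pd.DataFrame({
        "barcode": barcodes,
        "element_id": np.repeat(library["element_id"].to_numpy(), n_bc),
    })


def generate_counts(library: pd.DataFrame, truth: pd.DataFrame,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    barcode_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate DNA/RNA barcode counts per replicate and condition.

    Returns a long table (barcode, element_id, replicate, condition,
    dna, rna).  DNA is drawn once per replicate and shared across the
    two conditions; RNA is conditionally negative binomial around
    ``dna * 2**eta`` times the replicate/condition depth ratio.  A
    fraction ``outlier_barcode_rate`` of (barcode, replicate, condition)
    RNA values is inflated by ``outlier_factor`` to emulate jackpot
    barcodes.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    if barcode_map is None:
        barcode_map = assign_barcodes(library, config, rng)

    tr = truth.set_index("element_id")
    bm = barcode_map.merge(
        tr[["true_log2_alpha", "true_allelic_lfc", "true_interaction_beta"]],
        left_on="element_id", right_index=True, how="left",
    ).merge(library[["element_id", "allele"]], on="element_id", how="left")
    is_alt = (bm["allele"] == "alt").to_numpy(float)
    base = bm["true_log2_alpha"].to_numpy(float)
    lfc = bm["true_allelic_lfc"].to_numpy(float) * is_alt
    beta = bm["true_interaction_beta"].to_numpy(float) * is_alt
    n_bc = len(bm)
    R = config.n_replicates_per_condition

    dna_depth = 2.0 ** rng.normal(0.0, config.depth_log2_sd, size=R)
    rna_depth = 2.0 ** rng.normal(0.0, config.depth_log2_sd, size=(R, 2))

    frames = []
    for r in range(R):
        dna = _rnegbin(rng, np.full(n_bc, config.dna_mean * dna_depth[r]),
                       config.nb_dispersion)
        for ci, cond in enumerate(CONDITIONS):
            eta = base + lfc + beta * (cond == "stim")
            rna_mean = dna * (2.0 ** eta) * rna_depth[r, ci] / dna_depth[r]
            rna = _rnegbin(rng, rna_mean, config.nb_dispersion)
            if config.outlier_barcode_rate > 0:
                hit = rng.random(n_bc) < config.outlier_barcode_rate
                rna = np.where(hit, np.round(rna * config.outlier_factor), rna)
            frames.append(pd.DataFrame({
                "barcode": bm["barcode"], "element_id": bm["element_id"],
                "replicate": r + 1, "condition": cond,
                "dna": dna.astype(np.int64), "rna": rna.astype(np.int64),
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# side-annotations


@dataclass
class SyntheticAnnotations:
    """Fixture annotations with their own small truth records."""

    repeats: pd.DataFrame          # chrom,start,end,strand,name,class,family,milliDiv
    genes: pd.DataFrame            # gene_id,chrom,strand,tss (1-based)
    loops: pd.DataFrame            # BEDPE anchor columns
    pwms: dict[str, np.ndarray]    # motif_id -> 4 x w probability matrix
    planted_motif: dict            # motif_id, variant_ids whose ref matches
    expression: pd.DataFrame       # region x tf_gene mean expression
    gwas_regional: pd.DataFrame    # variant_id,tf_gene,region,z
    regional_truth: pd.DataFrame   # variant_id,tf_gene,slope
    de_table: pd.DataFrame = None  # gene_id,log2fc,fdr
    promoter_linked: list = field(default_factory=list)
    loop_linked: list = field(default_factory=list)


def generate_annotations(library: pd.DataFrame, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         regional_noise_sd: float = 0.0,
                         truth: pd.DataFrame | None = None,
                         ) -> SyntheticAnnotations:
    """Build repeat/gene/loop/PWM/regional fixtures consistent with the library."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)

    # Alu intervals covering the elements that embed boxes; length >= 250
    rep_rows = []
    alu_elems = library[(library["alu_mode"] != "") & (library["allele"] == "ref")]
    millidiv_choices = np.array([50, 120, 200])
    for k, (_, el) in enumerate(alu_elems.iterrows()):
        rep_rows.append(dict(
            chrom=el["chrom"], start=int(el["start"]) - 20,
            end=int(el["start"]) - 20 + 300, strand="+" if k % 4 else "-",
            repeat_name=f"AluY{k % 3}", repeat_class="SINE",
            repeat_family="Alu",
            milliDiv=int(millidiv_choices[k % 3]),
        ))
    # a few non-Alu repeats elsewhere
    non_alu = library[(library["alu_mode"] == "") & (library["allele"] == "ref")]
    for k, (_, el) in enumerate(non_alu.head(10).iterrows()):
        rep_rows.append(dict(
            chrom=el["chrom"], start=int(el["start"]) + 30,
            end=int(el["start"]) + 400, strand="+",
            repeat_name=f"L1M{k}", repeat_class="LINE", repeat_family="L1",
            milliDiv=int(rng.integers(30, 250)),
        ))
    repeats = pd.DataFrame(rep_rows)

    # genes: first few variants promoter-linked (+ strand TSS 500 bp right of
    # the element), next few loop-linked via BEDPE anchors
    variants = library[library["allele"] == "ref"].reset_index(drop=True)
    gene_rows, loop_rows = [], []
    promoter_linked, loop_linked = [], []
    n_prom = min(10, len(variants))
    n_loop = min(10, max(len(variants) - n_prom, 0))
    for i in range(n_prom):
        el = variants.iloc[i]
        tss = int(el["end"]) + 500  # element inside [TSS-2000, TSS)
        gene_rows.append(dict(gene_id=f"GENE_P{i:03d}", chrom=el["chrom"],
                              strand="+", tss=tss))
        promoter_linked.append((el["element_id"], f"GENE_P{i:03d}"))
    for i in range(n_prom, n_prom + n_loop):
        el = variants.iloc[i]
        gid = f"GENE_L{i:03d}"
        tss = int(el["start"]) + 500_000
        gene_rows.append(dict(gene_id=gid, chrom=el["chrom"], strand="+",
                              tss=tss))
        loop_rows.append(dict(
            chrom1=el["chrom"], start1=int(el["start"]) - 50,
            end1=int(el["end"]) + 50,
            chrom2=el["chrom"], start2=tss - 100, end2=tss + 100,
            name=f"loop{i}", score=1.0,
        ))
        loop_linked.append((el["element_id"], gid))
    genes = pd.DataFrame(gene_rows)
    loops = pd.DataFrame(loop_rows)

    # PWMs: a planted motif whose consensus equals the ref window of the
    # first variants, plus a background motif
    planted_variants = [variants.iloc[i]["variant_id"] for i in range(min(5, len(variants)))]
    w = 9
    half = w // 2
    pwms: dict[str, np.ndarray] = {}
    el0 = variants.iloc[0]
    core = el0["sequence"][VARIANT_OFFSET - half:VARIANT_OFFSET + half + 1]
    m = np.full((4, w), 0.02)
    for j, b in enumerate(core):
        m["ACGT".index(b), j] = 0.94
    pwms["PLANTED_TF"] = m / m.sum(axis=0, keepdims=True)
    rnd = rng.dirichlet(np.ones(4) * 0.5, size=8).T
    pwms["RANDOM_TF"] = rnd / rnd.sum(axis=0, keepdims=True)

    # regional TF expression and GWAS z with planted linear slopes
    regions = [f"region{r:02d}" for r in range(16)]
    tf_genes = ["TFA", "TFB"]
    expr = pd.DataFrame(
        rng.uniform(1.0, 5.0, size=(len(regions), len(tf_genes))),
        index=pd.Index(regions, name="region"), columns=tf_genes,
    )
    truth_rows, z_rows = [], []
    for vi, v in enumerate(planted_variants):
        tf = tf_genes[vi % len(tf_genes)]
        slope = 2.0 if vi % 2 == 0 else -1.5
        noise = rng.normal(0.0, regional_noise_sd, size=len(regions))
        z = slope * expr[tf].to_numpy() + noise
        for region, zz in zip(regions, z):
            z_rows.append(dict(variant_id=v, tf_gene=tf, region=region, z=zz))
        truth_rows.append(dict(variant_id=v, tf_gene=tf, slope=slope))
    gwas_regional = pd.DataFrame(z_rows)
    regional_truth = pd.DataFrame(truth_rows)

    # differential-expression fixture: genes linked to elements carrying a
    # planted condition interaction are DE with the same sign (concordant
    # coupling); the rest are null
    de_rows = []
    truth_by_element = (truth.set_index("element_id")["true_interaction_beta"]
                        if truth is not None else None)
    for eid, gid in promoter_linked + loop_linked:
        beta = float(truth_by_element.get(eid, 0.0)) if truth_by_element is not None else 0.0
        if beta != 0.0:
            de_rows.append(dict(gene_id=gid, log2fc=np.sign(beta) * 1.0,
                                fdr=0.01))
        else:
            de_rows.append(dict(gene_id=gid,
                                log2fc=float(rng.normal(0.0, 0.5)),
                                fdr=float(rng.uniform(0.0, 1.0))))
    de_table = pd.DataFrame(de_rows, columns=["gene_id", "log2fc", "fdr"])

    return SyntheticAnnotations(
        repeats=repeats, genes=genes, loops=loops, pwms=pwms,
        planted_motif={"motif_id": "PLANTED_TF", "variant_ids": planted_variants},
        expression=expr, gwas_regional=gwas_regional,
        regional_truth=regional_truth, de_table=de_table,
        promoter_linked=promoter_linked, loop_linked=loop_linked,
    )


# ---------------------------------------------------------------------------
# plain-text writers (BED half-open 0-based; GTF 1-based closed)


def write_library_fasta(library: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in library.iterrows():
            fh.write(f">{row['element_id']}\n{row['sequence']}\n")


def write_mapping_reads(library: pd.DataFrame, barcode_map: pd.DataFrame,
                        path, reads_per_barcode: int = 3) -> None:
    """Write barcode-mapping FASTQ reads: element 150-mer + 20 bp barcode."""
    seqs = library.set_index("element_id")["sequence"]
    with open(path, "w") as fh:
        i = 0
        for _, row in barcode_map.iterrows():
            read = seqs[row["element_id"]] + row["barcode"]
            for _ in range(reads_per_barcode):
                fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")
                i += 1


def write_repeatmasker_out(repeats: pd.DataFrame, path) -> None:
    """RepeatMasker .out dialect (3 header lines, whitespace columns)."""
    with open(path, "w") as fh:
        fh.write("   SW  perc perc perc  query      position in query"
                 "           matching       repeat\n")
        fh.write("score  div. del. ins.  sequence    begin     end    (left)"
                 "   repeat         class/family\n\n")
        for _, r in repeats.iterrows():
            strand = "+" if r["strand"] == "+" else "C"
            fh.write(
                f" 1000 {r['milliDiv'] / 10:5.1f}  0.0  0.0  {r['chrom']} "
                f"{int(r['start']) + 1} {int(r['end'])} (0) {strand} "
                f"{r['repeat_name']} {r['repeat_class']}/{r['repeat_family']} "
                f"1 300 (0) 1\n")


def write_repeats_bed(repeats: pd.DataFrame, path) -> None:
    """BED6+3: name=repeat_name, extra columns class, family, milliDiv."""
    cols = repeats[["chrom", "start", "end", "repeat_name", "milliDiv",
                    "strand", "repeat_class", "repeat_family"]]
    cols.to_csv(path, sep="\t", header=False, index=False)


def write_gtf(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            tss = int(g["tss"])
            start, end = (tss, tss + 1999) if g["strand"] == "+" else (tss - 1999, tss)
            fh.write(
                f"{g['chrom']}\tsynthetic\tgene\t{start}\t{end}\t.\t"
                f"{g['strand']}\t.\tgene_id \"{g['gene_id']}\";\n")


def write_bedpe(loops: pd.DataFrame, path) -> None:
    loops.to_csv(path, sep="\t", header=False, index=False)


def write_jaspar_pwms(pwms: dict[str, np.ndarray], path,
                      counts_scale: int = 100) -> None:
    with open(path, "w") as fh:
        for motif_id, mat in pwms.items():
            fh.write(f">{motif_id}\t{motif_id}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(str(int(round(v * counts_scale)))
                               for v in mat[bi])
                fh.write(f"{base}  [ {row} ]\n")
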