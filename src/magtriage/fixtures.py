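"""Synthetic, ground-truth-labelled input bundles plus the bundled worked example.

Every table the triage reads can be generated here with a known intended
outcome per MAG, so the whole pipeline is testable offline: labels are drawn
first (quality verdict, species/genus status, material category, congruence)
and values are then sampled inside label-consistent ranges, which keeps the
oracle unambiguous even at the 95%/65% boundaries. A single integer seed
drives one ``random.Random`` stream, so a bundle is byte-identical across
runs.

The worked example is the nine-MAG study set (one same-species MAG whose
closest reference is a cultivated but undeposited strain, eight novel
species with GTDB-classified in-silico references) with its printed
completeness, contamination, ANI and AAI values, shipped as module
constants and writable as a full input bundle.
"""

from __future__ import annotations

import math
import random
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from magtriage.io_formats import CANONICAL_RANKS

#: The nine-MAG worked-example study set. ``genes_present`` is the panel
#: presence count out of 115; ``aai_ref`` may differ from the ANI reference.
TABLE2 = [
    # mag_id, accession, size_mb, n_contigs, completeness, contamination,
    # gtdb_species_token, ani, ani_ref, aai, aai_ref, proposed_name,
    # category, genes_present, family, order
    {
        "mag_id": "W1-4_bin.70", "accession": "ERZ28674871", "size_mb": 6.30, "n_contigs": 227,
        "completeness": 98.82, "contamination": 0.47, "gtdb_species": "Kovacikia sp034541955",
        "ani": 99.6772, "ani_ref": "GCA_034541955.1", "aai": 82.8, "aai_ref": "GCA_034541955.1",
        "proposed_name": "Kovacikia ellensis", "category": "A3", "genes_present": 96,
        "family": "Leptolyngbyaceae", "order": "Leptolyngbyales",
    },
    {
        "mag_id": "W1-4_bin.36", "accession": "ERZ28674878", "size_mb": 7.88, "n_contigs": 195,
        "completeness": 99.04, "contamination": 1.59, "gtdb_species": "JAJPJF01 sp021324415",
        "ani": 81.405, "ani_ref": "GCA_021324415.1", "aai": 74.3, "aai_ref": "GCA_021324415.1",
        "proposed_name": "Paranostoc speluncae", "category": "B4", "genes_present": 100,
        "family": "Stigonemataceae", "order": "Nostocales",
    },
    {
        "mag_id": "S29-31_bin.74", "accession": "ERZ28674877", "size_mb": 7.66, "n_contigs": 587,
        "completeness": 96.75, "contamination": 1.81, "gtdb_species": "Aetokthonos hydrillicola",
        "ani": 85.3098, "ani_ref": "GCA_017591595.2", "aai": 79.5, "aai_ref": "GCA_017591595.2",
        "proposed_name": "Aetokthonos rifticola", "category": "B4", "genes_present": 99,
        "family": "Scytonemataceae", "order": "Nostocales",
    },
    {
        "mag_id": "S29-31_bin.60", "accession": "ERZ28674876", "size_mb": 6.44, "n_contigs": 173,
        "completeness": 97.56, "contamination": 3.22, "gtdb_species": "JAFAVL01 sp019244235",
        "ani": 94.3411, "ani_ref": "GCA_019244235.1", "aai": 76.9, "aai_ref": "GCA_019242465.1",
        "proposed_name": "Chroococcidiopsis rifticola", "category": "B4", "genes_present": 99,
        "family": "Chroococcidiopsidaceae", "order": "Chroococcidiopsidales",
    },
    {
        "mag_id": "HW-12_bin.40", "accession": "ERZ28674869", "size_mb": 5.72, "n_contigs": 367,
        "completeness": 96.89, "contamination": 2.23, "gtdb_species": "Prochlorococcus_A sp001989455",
        "ani": 86.9307, "ani_ref": "GCA_000635355.1", "aai": 65.9, "aai_ref": "GCA_023558375.1",
        "proposed_name": "Chroococcidiopsis edaphicus", "category": "B4", "genes_present": 98,
        "family": "Chroococcidiopsidaceae", "order": "Chroococcidiopsidales",
    },
    {
        "mag_id": "S29-31_bin.237", "accession": "ERZ28674875", "size_mb": 7.83, "n_contigs": 105,
        "completeness": 98.67, "contamination": 1.56, "gtdb_species": "JANRIL01 sp033764955",
        "ani": 79.1589, "ani_ref": "GCA_033764955.1", "aai": 71.1, "aai_ref": "GCA_964657555.1",
        "proposed_name": "Microcoleus pahoaensis", "category": "B4", "genes_present": 100,
        "family": "Microcoleaceae", "order": "Oscillatoriales",
    },
    {
        "mag_id": "S29-31_bin.125", "accession": "ERZ28674874", "size_mb": 6.86, "n_contigs": 283,
        "completeness": 98.82, "contamination": 2.2, "gtdb_species": "MUGG01 sp014697025",
        "ani": 79.9028, "ani_ref": "GCA_014697025.1", "aai": 74.3, "aai_ref": "GCA_000733415.1",
        "proposed_name": "Elainella pahoaensis", "category": "B4", "genes_present": 97,
        "family": "Oculatellaceae", "order": "Oculatellales",
    },
    {
        "mag_id": "S13-15_bin.75", "accession": "ERZ28674873", "size_mb": 6.81, "n_contigs": 326,
        "completeness": 98.92, "contamination": 0.44, "gtdb_species": "Brasilonema sp019359415",
        "ani": 89.9154, "ani_ref": "GCA_019359415.1", "aai": 78.1, "aai_ref": "GCA_019359415.1",
        "proposed_name": "Brasilonema rifticola", "category": "B4", "genes_present": 99,
        "family": "Scytonemataceae", "order": "Nostocales",
    },
    {
        "mag_id": "P23-25_bin.64", "accession": "ERZ28674872", "size_mb": 7.54, "n_contigs": 213,
        "completeness": 97.41, "contamination": 0.71, "gtdb_species": "Leptodesmis sp037442585",
        "ani": 79.7857, "ani_ref": "GCA_037442585.1", "aai": 77.2, "aai_ref": "GCA_021379005.1",
        "proposed_name": "Leptodesmis pahoaensis", "category": "B4", "genes_present": 98,
        "family": "Leptolyngbyaceae", "order": "Leptolyngbyales",
    },
]

#: Ids of the two bins dropped at the photosynthesis-exclusion step
#: (relatives of the non-photosynthetic Vampirovibrionophyceae).
NON_PHOTOSYNTHETIC_EXCLUSIONS = [
    ("S29-31_bin.128", "potential Vampirovibrionophyceae"),
    ("P18-20_bin.4", "potential Vampirovibrionophyceae"),
]

_STATUSES = ("type_strain", "public_collection_strain", "cultivated_undeposited", "in_silico")
_ORDERS = ("Nostocales", "Leptolyngbyales", "Oscillatoriales", "Chroococcidiopsidales", "Oculatellales")


class FixtureConfig(BaseModel):
    """Knobs of the synthetic-bundle generator.

    The ANI ranges default to the label-consistent intervals around the 95%
    species boundary ([95, 100) for same-species MAGs, [75, 95) for novel
    ones); the other mixes emulate the spread of material categories and
    lineage resolutions a reference database presents.
    """

    n_mags: int = Field(default=10, ge=1)
    n_references: int = Field(default=30, ge=1)
    fraction_novel: float = Field(default=0.5, ge=0.0, le=1.0)
    ani_known_range: tuple[float, float] = (95.0, 100.0)
    ani_novel_range: tuple[float, float] = (75.0, 95.0)
    material_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "type_strain": 0.15,
            "public_collection_strain": 0.15,
            "cultivated_undeposited": 0.15,
            "in_silico": 0.55,
        }
    )
    lineage_depth_mix: dict[str, float] = Field(
        default_factory=lambda: {"species": 0.5, "genus": 0.2, "family": 0.2, "order": 0.1}
    )
    p_gtdb_hit: float = Field(default=0.5, ge=0.0, le=1.0)
    p_incongruent: float = Field(default=0.3, ge=0.0, le=1.0)
    fraction_fail_quality: float = Field(default=0.15, ge=0.0, le=1.0)
    fraction_novel_genus: float = Field(default=0.2, ge=0.0, le=1.0)
    panel_dropout: float = Field(default=0.1, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self) -> "FixtureConfig":
        for name, (lo, hi) in (("ani_known_range", self.ani_known_range), ("ani_novel_range", self.ani_novel_range)):
            if not (0.0 <= lo < hi <= 100.0):
                raise ValueError(f"{name} must satisfy 0 <= lo < hi <= 100")
        if self.ani_novel_range[1] > 95.0 or self.ani_known_range[0] < 95.0:
            raise ValueError("ANI ranges must be disjoint at the 95 species boundary")
        for name, mix in (("material_mix", self.material_mix), ("lineage_depth_mix", self.lineage_depth_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if set(self.material_mix) != set(_STATUSES):
            raise ValueError(f"material_mix must cover exactly {_STATUSES}")
        bad = set(self.lineage_depth_mix) - set(CANONICAL_RANKS)
        if bad:
            raise ValueError(f"lineage_depth_mix has non-canonical ranks {bad}")
        return self


def _choose(rng: random.Random, mix: dict[str, float]) -> str:
    x = rng.random()
    acc = 0.0
    items = sorted(mix.items())
    for key, p in items:
        acc += p
        if x < acc:
            return key
    return items[-1][0]


def _in_range(rng: random.Random, lo: float, hi: float) -> float:
    # half-open sample truncated (not rounded) to 4 decimals, so the value
    # printed with %.4f can never cross the upper label boundary
    value = lo + rng.random() * (hi - lo)
    return math.floor(value * 10_000) / 10_000


def _gtdb_lineage(order: str, family: str, genus: Optional[str], species: Optional[str]) -> str:
    parts = ["d__Bacteria", "p__Cyanobacteriota", "c__Cyanophyceae", f"o__{order}", f"f__{family}"]
    if genus:
        parts.append(f"g__{genus}")
        if species:
            parts.append(f"s__{species}")
    return ";".join(parts)


def _ncbi_lineage(order: Optional[str], family: Optional[str], genus: Optional[str]) -> str:
    parts = ["Bacteria", "Cyanobacteriota", "Cyanophyceae"]
    if order:
        parts.append(order)
        if family:
            parts.append(family)
            if genus:
                parts.append(genus)
    return "; ".join(parts)


def _tblout_line(protein: str, model: str, evalue: float, score: float) -> str:
    head = f"{protein} - {model} -"
    stats = f"{evalue:.1e} {score:.1f} 0.1 {evalue:.1e} {score:.1f} 0.1"
    tail = "1.0 1 1 0 1 1 1 1 synthetic hit"
    return f"{head} {stats} {tail}"


def generate_fixture(cfg: FixtureConfig, outdir: str | Path) -> Path:
    """Write a complete synthetic input bundle plus its ground-truth label table.

    Labels are drawn first, values second, so the label table is an exact
    oracle for an end-to-end run. Returns the path of ``labels.tsv``.
    """
    from magtriage.gene_panel import load_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tblout").mkdir(exist_ok=True)
    (outdir / "fasta").mkdir(exist_ok=True)
    rng = random.Random(cfg.seed)
    panel = load_panel()

    quality_rows = ["mag_id\tcompleteness\tcontamination\tgunc_css\tgunc_contamination"]
    ani_rows: list[str] = []
    aai_rows: list[str] = []
    tax_rows: list[str] = []
    mat_rows: list[str] = []
    pair_rows: list[str] = []
    label_rows = [
        "mag_id\tquality_pass\tspecies_status\tgenus_status\tmaterial_index\tcongruent\tcategory\tn_panel_present"
    ]
    mag_ids: list[str] = []

    for i in range(cfg.n_mags):
        mag = f"MAG_{i:03d}"
        mag_ids.append(mag)
        ref = f"GCA_{900000 + i:07d}.1"
        order = _ORDERS[i % len(_ORDERS)]
        family = f"Family{i:03d}"
        genus = f"Genus{i:03d}"

        # --- draw the intended labels
        fail_quality = rng.random() < cfg.fraction_fail_quality
        novel = rng.random() < cfg.fraction_novel
        status = _choose(rng, cfg.material_mix)
        gtdb_hit = status != "in_silico" or rng.random() < cfg.p_gtdb_hit
        if status != "in_silico":
            index = {"type_strain": 1, "public_collection_strain": 2, "cultivated_undeposited": 3}[status]
        else:
            index = 4 if gtdb_hit else 5
        congruent = True if index != 5 else rng.random() >= cfg.p_incongruent
        novel_genus = rng.random() < cfg.fraction_novel_genus
        depth = _choose(rng, cfg.lineage_depth_mix)
        if index == 5 and congruent and CANONICAL_RANKS.index(depth) < CANONICAL_RANKS.index("family"):
            depth = "family"  # three-hit congruence needs the best hit named to family
        if not novel_genus and CANONICAL_RANKS.index(depth) < CANONICAL_RANKS.index("genus"):
            genus_status = "unresolved"
        elif novel_genus:
            genus_status = "novel_genus"
        else:
            genus_status = "existing_genus"

        # --- sample values inside label-consistent ranges
        if fail_quality:
            if rng.random() < 0.5:
                completeness, contamination = _in_range(rng, 50.0, 89.9), _in_range(rng, 0.0, 4.5)
            else:
                completeness, contamination = _in_range(rng, 96.0, 99.9), _in_range(rng, 5.1, 15.0)
        else:
            completeness, contamination = _in_range(rng, 96.0, 99.9), _in_range(rng, 0.0, 4.5)
        lo, hi = cfg.ani_novel_range if novel else cfg.ani_known_range
        ani = _in_range(rng, lo, hi)
        aai = _in_range(rng, 55.0, 64.9) if novel_genus else _in_range(rng, 65.0, 90.0)
        species_status = "novel_species" if novel else "known_species"
        if fail_quality:
            category = "FAIL_QUALITY"
        elif index == 5 and not congruent:
            category = "REJECT_INCONGRUENT"
        else:
            category = ("B" if novel else "A") + str(index)

        # --- emit the rows
        quality_rows.append(
            f"{mag}\t{completeness:.4f}\t{contamination:.4f}\t{rng.random() * 0.4:.4f}\t{_in_range(rng, 0, 3):.4f}"
        )
        total_frag = 1500 + i * 7
        mapped = int(total_frag * ani / 100.0)
        ani_rows.append(f"{mag}\t{ref}\t{ani:.4f}\t{mapped}\t{total_frag}")
        decoy = f"GCA_{800000 + i:07d}.1"
        decoy_ani = max(40.0, ani - 0.5 - 5.0 * rng.random())
        ani_rows.append(f"{mag}\t{decoy}\t{decoy_ani:.4f}\t{int(total_frag * decoy_ani / 100)}\t{total_frag}")
        aai_rows.append(f"{mag}\t{ref}\t{aai:.4f}")

        # taxonomy of the best reference: depth per the genus label
        depth_i = CANONICAL_RANKS.index(depth)
        lin_genus = genus if depth_i >= CANONICAL_RANKS.index("genus") else None
        lin_species = f"{genus} sp{900000 + i}" if depth == "species" else None
        lin_family = family if depth_i >= CANONICAL_RANKS.index("family") else None
        if gtdb_hit:
            tax_rows.append(f"{ref}\tGTDB\t{_gtdb_lineage(order, lin_family or family, lin_genus, lin_species)}")
        tax_rows.append(f"{ref}\tNCBI\t{_ncbi_lineage(order, lin_family, lin_genus)}")

        if index == 5:
            # two runner-up NCBI hits for the three-hit congruence check
            for j in (2, 3):
                extra_ref = f"GCA_{700000 + 10 * i + j:07d}.1"
                extra_aai = max(40.0, aai - j * (0.5 + rng.random()))
                aai_rows.append(f"{mag}\t{extra_ref}\t{extra_aai:.4f}")
                if congruent:
                    lin = _ncbi_lineage(order, family, f"{genus}x{j}")
                else:
                    lin = _ncbi_lineage(f"OtherOrder{j}", f"OtherFamily{i}x{j}", None)
                tax_rows.append(f"{extra_ref}\tNCBI\t{lin}")

        collections = "CC:" + mag if status == "public_collection_strain" else ""
        code = "ICNP" if status == "type_strain" else ""
        mat_rows.append(f"{ref}\t{status}\t{collections}\t{code}")

        # panel search output; eukaryote-specific genes are never hit
        dropped = 0
        tbl_lines = [
            "#                                                               --- full sequence ---- --- best 1 domain ---- --- domain number estimation ----",
            "# target name        accession  query name           accession    E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target",
        ]
        k = 0
        for entry in panel:
            if entry.eukaryote_specific:
                continue
            if rng.random() < cfg.panel_dropout:
                dropped += 1
                continue
            k += 1
            tbl_lines.append(_tblout_line(f"{mag}_p{k:04d}", entry.model_id, 1e-40 * (1 + i), 200.0 + k))
        (outdir / "tblout" / f"{mag}.tbl").write_text("\n".join(tbl_lines) + "\n")
        n_euk = sum(1 for e in panel if e.eukaryote_specific)
        n_present = len(panel) - n_euk - dropped

        with (outdir / "fasta" / f"{mag}.fasta").open("w") as fh:
            for c in range(rng.randint(3, 5)):
                length = rng.randint(200, 1500)
                seq = "".join(rng.choice("ACGT") for _ in range(length))
                fh.write(f">{mag}_contig{c}\n{seq}\n")

        label_rows.append(
            f"{mag}\t{int(not fail_quality)}\t{species_status}\t{genus_status}\t{index}\t{int(congruent)}\t{category}\t{n_present}"
        )

    for a in range(len(mag_ids)):
        for b in range(a + 1, len(mag_ids)):
            pair_rows.append(f"{mag_ids[a]}\t{mag_ids[b]}\t{_in_range(rng, 80.0, 93.0):.4f}")

    (outdir / "quality.tsv").write_text("\n".join(quality_rows) + "\n")
    (outdir / "ani.tsv").write_text("\n".join(ani_rows) + "\n")
    (outdir / "aai.tsv").write_text("\n".join(aai_rows) + "\n")
    (outdir / "taxonomy.tsv").write_text("\n".join(tax_rows) + "\n")
    (outdir / "materials.tsv").write_text("\n".join(mat_rows) + "\n")
    (outdir / "pairwise_ani.tsv").write_text("\n".join(pair_rows) + "\n")
    labels = outdir / "labels.tsv"
    labels.write_text("\n".join(label_rows) + "\n")
    return labels


def table2_fixture(outdir: str | Path) -> Path:
    """Write the nine-MAG worked-example study set as a full input bundle.

    One MAG matches (ANI 99.68%) a cultivated but undeposited strain and is
    expected at category A3; the other eight sit below 95% ANI with
    GTDB-classified in-silico references and are expected at B4. Returns the
    path of ``labels.tsv`` (mag_id, category).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    quality_rows = ["mag_id\tcompleteness\tcontamination\tgenome_size\tn_contigs"]
    ani_rows: list[str] = []
    aai_rows: list[str] = []
    tax_rows: list[str] = []
    mat_rows: list[str] = []
    label_rows = ["mag_id\tcategory"]
    for row in TABLE2:
        quality_rows.append(
            f"{row['mag_id']}\t{row['completeness']}\t{row['contamination']}"
            f"\t{int(round(row['size_mb'] * 1e6))}\t{row['n_contigs']}"
        )
        total = 2300
        ani_rows.append(f"{row['mag_id']}\t{row['ani_ref']}\t{row['ani']}\t{int(total * row['ani'] / 100)}\t{total}")
        aai_rows.append(f"{row['mag_id']}\t{row['aai_ref']}\t{row['aai']}")
        tax_rows.append(f"{row['ani_ref']}\tGTDB\ts__{row['gtdb_species']}")
        status = "cultivated_undeposited" if row["category"] == "A3" else "in_silico"
        mat_rows.append(f"{row['ani_ref']}\t{status}\t\t")
        label_rows.append(f"{row['mag_id']}\t{row['category']}")
    (outdir / "quality.tsv").write_text("\n".join(quality_rows) + "\n")
    (outdir / "ani.tsv").write_text("\n".join(ani_rows) + "\n")
    (outdir / "aai.tsv").write_text("\n".join(aai_rows) + "\n")
    (outdir / "taxonomy.tsv").write_text("\n".join(tax_rows) + "\n")
    (outdir / "materials.tsv").write_text("\n".join(mat_rows) + "\n")
    labels = outdir / "labels.tsv"
    labels.write_text("\n".join(label_rows) + "\n")
    return labels
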