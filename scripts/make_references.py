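"""Generate the synthetic stand-in reference sequences and the variant
definition table shipped as package data.

The references are random sequences of the correct lengths with the
catalogue's wild-type base planted at every catalogued position. Indel
contexts are constrained so that each catalogued indel is already at its
left-most equivalent placement, which makes planted variants round-trip
through alignment, extraction, left-normalization and naming to exactly
the catalogued name. Run once from the repository root; outputs are
committed under src/deafscreen/data/.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

DATA = Path(__file__).resolve().parents[1] / "src" / "deafscreen" / "data"
BASES = np.array(list("ACGT"))
SEED = 20130704  # fixed: the references are versioned package data

GJB2_CDS_LEN = 678  # connexin-26 coding sequence length (226 codons)
EX1_LEN = 320  # exon-1 + basal-promoter amplicon stand-in
MT_START, MT_END = 601, 1620  # m. coordinates covered by the 12S region

# wild-type bases required at catalogued positions (1-based c. / m.)
GJB2_FIXED = {
    35: "G", 79: "G", 101: "T", 109: "G", 235: "C", 257: "C",
    299: "A", 300: "T", 341: "A", 368: "C", 571: "T", 608: "T", 609: "C",
}
MT_FIXED = {
    663: "A", 681: "T", 709: "G", 735: "A", 750: "A", 752: "C", 789: "T",
    827: "A", 961: "T", 979: "C", 1005: "T", 1009: "C", 1040: "T",
    1041: "A", 1048: "C", 1095: "T", 1107: "T", 1119: "T", 1187: "T",
    1222: "A", 1282: "G", 1382: "A", 1415: "G", 1438: "A", 1494: "C",
    1520: "T", 1555: "A", 1598: "G",
}
# position -> base that must NOT occur there (blocks indel left-shift)
GJB2_FORBIDDEN = {
    34: "G",    # keeps c.35delG anchored at 35
    234: "C",   # keeps c.235delC anchored at 235
    298: "T",   # keeps c.299delAT anchored at 299
    504: "G",   # keeps c.504insAAGG anchored at 504
}


def random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(BASES[rng.integers(0, 4, n)])


def build_gjb2(rng: np.random.Generator) -> str:
    seq = random_seq(rng, GJB2_CDS_LEN)
    for pos, b in GJB2_FIXED.items():
        seq[pos - 1] = b
    for pos, bad in GJB2_FORBIDDEN.items():
        while seq[pos - 1] == bad:
            seq[pos - 1] = str(rng.choice(BASES))
    # keep c.176del16 anchored at 176: flanking base must differ from the
    # last deleted base
    while seq[175 - 1] == seq[191 - 1]:
        seq[175 - 1] = str(rng.choice(BASES))
    return "".join(seq)


def build_mt(rng: np.random.Generator) -> str:
    seq = random_seq(rng, MT_END - MT_START + 1)
    for pos, b in MT_FIXED.items():
        seq[pos - MT_START] = b
    return "".join(seq)


def write_fasta(path: Path, header: str, seq: str) -> None:
    lines = [f">{header}"]
    lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
    path.write_text("\n".join(lines) + "\n")


GJB2_ANNOT = [
    # name, aa_change, domain, category, polyphen, sift, previously_reported
    ("c.35delG", "Frameshift", "IC1", "pathogenic", "", "", "yes"),
    ("c.79G>A", "Val27Ile", "TM1", "polymorphism", "1.000", "0.15", "yes"),
    ("c.101T>C", "Met34Thr", "TM1", "polymorphism", "0.038", "0.12", "yes"),
    ("c.109G>A", "Val37Ile", "TM1", "pathogenic", "1.000", "0.12", "yes"),
    ("c.176del16", "Frameshift", "EC1", "pathogenic", "", "", "yes"),
    ("c.235delC", "Frameshift", "TM2", "pathogenic", "", "", "yes"),
    ("c.257C>G", "Thr86Arg", "TM2", "pathogenic", "1.000", "0.00", "no"),
    ("c.299delAT", "Frameshift", "IC2", "pathogenic", "", "", "yes"),
    ("c.341A>G", "Glu114Gly", "IC2", "polymorphism", "0.001", "0.27", "yes"),
    ("c.368C>A", "Thr123Asn", "IC2", "unknown", "0.000", "0.53", "yes"),
    ("c.504insAAGG", "Frameshift", "EC2", "pathogenic", "", "", "yes"),
    ("c.571T>C", "Phe191Leu", "EC2", "unknown", "1.000", "0.00", "yes"),
    ("c.605ins46", "Stop at aa 202", "TM4", "pathogenic", "", "", "yes"),
    ("c.608TC>AA", "Ile203Lys", "TM4", "pathogenic", "", "0.00", "yes"),
    ("c.608T>C", "Ile203Thr", "TM4", "polymorphism", "0.906", "0.00", "yes"),
]

# mitochondrial catalogue categories: the literature-confirmed deafness
# mutations (m.1555A>G, m.1494C>T, m.1095T>C and the position-961 changes)
# are pathogenic; m.1222A>G is the novel variant; the rest are unannotated.
MT_PATHOGENIC = {
    "m.961insC", "m.961delT+insC", "m.961T>C",
    "m.1095T>C", "m.1494C>T", "m.1555A>G",
}
MT_NAMES = [
    "m.663A>G", "m.681T>C", "m.709G>A", "m.735A>G", "m.750A>G", "m.752C>T",
    "m.789T>C", "m.827A>G", "m.961insC", "m.961delT+insC", "m.961T>C",
    "m.979C>T", "m.1005T>C", "m.1009C>T", "m.1040T>C", "m.1041A>G",
    "m.1048C>T", "m.1095T>C", "m.1107T>C", "m.1119T>C", "m.1187T>C",
    "m.1222A>G", "m.1282G>A", "m.1382A>C", "m.1415G>A", "m.1438A>G",
    "m.1494C>T", "m.1520T>C", "m.1555A>G", "m.1598G>A",
]


def main() -> None:
    from deafscreen.calling import parse_variant_name

    rng = np.random.default_rng(SEED)
    gjb2 = build_gjb2(rng)
    ex1 = "".join(random_seq(rng, EX1_LEN))
    mt = build_mt(rng)

    # 46-base insert of c.605ins46; last base must differ from the base at
    # c.605 so the insertion cannot left-shift
    while True:
        ins46 = "".join(random_seq(rng, 46))
        if ins46[-1] != gjb2[605 - 1]:
            break

    write_fasta(DATA / "gjb2_cds.fasta", "GJB2|CDS|offset=0", gjb2)
    write_fasta(DATA / "gjb2_promoter_exon1.fasta", "GJB2_EX1|promoter_exon1|offset=0", ex1)
    write_fasta(DATA / "mt12s.fasta", f"MT12S|12S_region|offset={MT_START - 1}", mt)

    rows = []
    for name, aa, dom, cat, pp, sift, prev in GJB2_ANNOT:
        p = parse_variant_name(name)
        pos = p["position"]
        if p["kind"] == "deletion":
            ref = gjb2[pos - 1 : pos - 1 + p.get("length", len(p.get("ref", "")))]
            alt = ""
        elif p["kind"] == "insertion":
            ref = ""
            alt = p.get("alt", ins46 if p.get("length") == 46 else "")
        else:
            ref, alt = p["ref"], p["alt"]
        rows.append((name, "GJB2", p["kind"], pos, ref, alt, cat, dom, aa, prev, pp, sift, ""))
    for name in MT_NAMES:
        p = parse_variant_name(name)
        pos = p["position"]
        cat = (
            "pathogenic" if name in MT_PATHOGENIC
            else "novel" if name == "m.1222A>G"
            else "unknown"
        )
        prev = "no" if name == "m.1222A>G" else "yes"
        equiv = ""
        if p["kind"] == "delins":
            # m.961delT+insC is molecularly the T>C exchange at 961; the
            # historic combined spelling is kept as the catalogue name
            kind, ref, alt, equiv = "substitution", p["ref"], p["alt"], "m.961T>C"
        elif p["kind"] == "deletion":
            kind, ref, alt = p["kind"], mt[pos - MT_START], ""
        elif p["kind"] == "insertion":
            kind, ref, alt = p["kind"], "", p["alt"]
        else:
            kind, ref, alt = p["kind"], p["ref"], p["alt"]
        rows.append((name, "MT12S", kind, pos, ref, alt, cat, "", "", prev, "", "", equiv))

    header = (
        "name\tlocus\tkind\tposition\tref_allele\talt_allele\tcategory\t"
        "domain_label\taa_change\tpreviously_reported\tpolyphen_score\t"
        "sift_score\tequivalent_to"
    )
    out = ["# Variant definition and annotation catalogue (both loci)."]
    out.append("# ref_allele/alt_allele are resolved against the synthetic references.")
    out.append(header)
    out += ["\t".join(str(x) for x in r) for r in rows]
    (DATA / "variants.tsv").write_text("\n".join(out) + "\n")

    # self-check: every substitution's stated wild-type base matches the
    # reference it was planted into
    for r in rows:
        if r[2] in ("substitution", "mnv_substitution"):
            seq, off = (gjb2, 0) if r[1] == "GJB2" else (mt, MT_START - 1)
            got = seq[r[3] - off - 1 : r[3] - off - 1 + len(r[4])]
            assert got == r[4], (r[0], got)
    print(f"wrote references and {len(rows)} variant definitions to {DATA}")


if __name__ == "__main__":
    main()
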