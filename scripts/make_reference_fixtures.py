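"""One-off generator for the packaged synthetic reference fixtures.

Run from the repository root. 

Produces src/tcrrep/data/germline_trb_synthetic.fasta (12 V / 2 D / 13 J)
and src/tcrrep/data/patcr_synthetic.csv. Deterministic (seeded).
"""
import itertools
import numpy as np

rng = np.random.default_rng(20211125)
NT = np.array(list("ACGT"))


def rand_nt(n):
    return "".join(rng.choice(NT, size=n))


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


# ---- V segments: 30 nt lead + Cys codon + 12 nt tail (anchor_offset=30) ----
# Tails must diverge early so that short retained prefixes discriminate genes.
tails = []
first3_seen = set()
while len(tails) < 12:
    t = rand_nt(12)
    if "GGGG" in t or "CCCC" in t:
        continue  # avoid D-like homopolymer runs inside V tails
    if t[:3] in first3_seen:
        continue
    if any(hamming(t, u) < 7 for u in tails):
        continue
    tails.append(t)
    first3_seen.add(t[:3])

v_records = []
for i, tail in enumerate(tails, start=1):
    lead = rand_nt(30)
    cys = "TGT" if i % 2 else "TGC"
    v_records.append((f"TRBVS{i}", "V", lead + cys + tail, 30))

# ---- D segments: short GC-rich cores (synthetic stand-ins) ----
d_records = [
    ("TRBDS1", "D", "GGGACAGGGGGC", None),
    ("TRBDS2", "D", "GGGACTAGCGGGAGGG", None),
]

# ---- J segments: 12 nt head + Phe codon + 12 nt tail (anchor_offset=12) ----
heads = []
last3_seen = set()
while len(heads) < 13:
    h = rand_nt(12)
    if "GGGG" in h or "CCCC" in h:
        continue
    if h[-3:] in last3_seen:
        continue
    if any(hamming(h, u) < 7 for u in heads):
        continue
    heads.append(h)
    last3_seen.add(h[-3:])

j_records = []
for i, head in enumerate(heads, start=1):
    phe = "TTC" if i % 2 else "TTT"
    tail = rand_nt(12)
    j_records.append((f"TRBJS{i}", "J", head + phe + tail, 12))

with open("src/tcrrep/data/germline_trb_synthetic.fasta", "w") as fh:
    for name, cls, seq, anchor in itertools.chain(v_records, d_records, j_records):
        header = f">{name}|{cls}" + (f"|anchor={anchor}" if anchor is not None else "")
        fh.write(header + "\n" + seq + "\n")

# ---- synthetic paTCR table (TBAdb/McPAS-like schema) ----
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
diseases = [
    ("pathogen", "Cytomegalovirus", 6),
    ("pathogen", "Epstein-Barr virus", 5),
    ("pathogen", "Influenza A", 5),
    ("pathogen", "Mycobacterium tuberculosis", 4),
    ("autoimmune_allergy", "Multiple sclerosis", 6),
    ("autoimmune_allergy", "Type 1 diabetes", 5),
    ("autoimmune_allergy", "Celiac disease", 4),
    ("cancer", "Melanoma", 6),
    ("cancer", "Non-small-cell lung cancer", 4),
    ("cancer", "Breast cancer", 4),
    ("other", "Aseptic meningitis", 4),
    ("other", "Transverse myelitis", 4),
    ("other", "Muscular dystrophy", 4),
]
seen = set()
rows = []
for category, disease, n in diseases:
    for _ in range(n):
        while True:
            mid = "".join(rng.choice(AA, size=int(rng.integers(7, 11))))
            cdr3 = "CASS" + mid + "F"
            if cdr3 not in seen:
                seen.add(cdr3)
                break
        rows.append((cdr3, category, disease))

with open("src/tcrrep/data/patcr_synthetic.csv", "w") as fh:
    fh.write("cdr3_aa,category,disease\n")
    for cdr3, category, disease in rows:
        fh.write(f"{cdr3},{category},{disease}\n")

print("V tails:", [t for t in tails])
print("J heads:", [h for h in heads])
print("rows:", len(rows))
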