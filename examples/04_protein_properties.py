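"""Molecular weight and isoelectric point with ProtParam conventions.

Average residue masses plus one water give the chain mass; the isoelectric
point is the pH where the Henderson-Hasselbalch net charge (Bjellqvist pKa
set) crosses zero, found by bisection.
"""

import famscan as fs

peptides = {
    "glycine": "G",
    "diglycine": "GG",
    "acidic-rich": "MDDEEDDSSE",
    "basic-rich": "MKKRRHKKGR",
}

print(f"{'peptide':12s} {'MW (Da)':>10s} {'pI':>7s} {'class':>8s}")
for name, seq in peptides.items():
    mw = fs.molecular_weight(seq)
    pi = fs.isoelectric_point(seq)
    print(f"{name:12s} {mw:10.2f} {pi:7.3f} {fs.pi_class(pi):>8s}")

pi = fs.isoelectric_point("MKKRRHKKGR")
print(f"\nnet charge at its own pI: {fs.net_charge('MKKRRHKKGR', pi):+.4f} (~0)")
# Basic-rich sequences isolate above pH 7.5 ("basic"), acidic-rich below 6.5;
# the family inventory's pI column follows exactly these conventions.
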