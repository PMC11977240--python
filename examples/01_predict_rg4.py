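"""Predict QGRS-style RG4 motifs in a few RNA sequences and score them.

The scorer rewards extra G-tetrads and short, even loops; sites scoring
>= 21 are the conventional high-confidence set.
"""

from rg4coloc import filter_by_score, predict_qgrs

sequences = {
    "canonical_3tetrad": "GGGAGGGAGGGAGGG",
    "two_tetrad_short_loops": "GGAGGAGGAGG",
    "uneven_loops": "GGGAAAAAGGGAGGGAAGGG",
    "no_quadruplex": "GGAGGAGGACCACUAGU",
}

for name, seq in sequences.items():
    sites = predict_qgrs(seq)
    print(f"{name}  ({seq})")
    if not sites:
        print("   no QGRS found")
    for s in sites:
        print(
            f"   [{s.start},{s.end})  tetrads={s.tetrads}  score={s.score}"
            f"  {'(high-confidence, >= 21)' if s.score >= 21 else ''}"
        )
    print()

high = filter_by_score(predict_qgrs(sequences["uneven_loops"]), 21)
print(f"high-scoring sites in 'uneven_loops': {len(high)}")
print("A score drops as loops lengthen or become uneven; a third tetrad adds 12.")
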