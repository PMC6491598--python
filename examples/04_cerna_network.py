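"""ceRNA pairing by shared miRNAs: a PPCK-style focal-gene query.

A focal mRNA is perfectly bound by two miRNAs; five lncRNAs carry mimic
sites for those miRNAs, so each can titrate the miRNAs away from the mRNA.
"""

import pandas as pd

from camlnc import BindingTable, focal_cerna, shared_mirna_pairs

records = (
    [("miR-a", "PPCK", "perfect"), ("miR-b", "PPCK", "perfect")]
    + [("miR-a", f"lnc{i}", "mimic") for i in (1, 2, 3)]
    + [("miR-b", f"lnc{i}", "mimic") for i in (4, 5)]
)
bindings = BindingTable(pd.DataFrame(records, columns=["mirna", "transcript", "mode"]))

pairs, competed = focal_cerna(bindings, "PPCK")
print(f"PPCK has {len(pairs)} ceRNA partners competing for {len(competed)} miRNAs:")
for p in pairs:
    partner = p.transcript_b if p.transcript_a == "PPCK" else p.transcript_a
    print(f"  {partner}: {p.pair_type} via {sorted(p.shared_mirnas)}")
print("A target-mimic pair joins a perfectly-bound target and an "
      "imperfectly-bound decoy of the same miRNA.")
print(f"all pairs in the table: {len(shared_mirna_pairs(bindings))} "
      "(decoy-decoy mimic pairs are excluded)")
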