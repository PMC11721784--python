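"""Filter homology hits and scan a flank for transposon target-site motifs.

Homology searches for a young ORF return many marginal hits; the stringency
filter keeps only hits with E <= 1e-5, identity >= 60 % and query coverage
>= 70 %.  The TSD scan looks for short direct-repeat remnants (here CATGGC)
upstream of the start codon, evidence of ancient transposition at the locus.
"""

import numpy as np

from denovopop.io_formats import SequenceRecord
from denovopop.orf_evolution import HomologyHit, filter_homology_hits, scan_tsd

hits = [
    HomologyHit("orf", "species_A", 92.0, 210, 1e-40, 98.0),
    HomologyHit("orf", "species_B", 61.5, 150, 3e-8, 74.0),
    HomologyHit("orf", "species_C", 59.9, 200, 1e-30, 95.0),   # identity < 60
    HomologyHit("orf", "species_D", 88.0, 80, 2e-3, 90.0),     # E-value too weak
]
retained = filter_homology_hits(hits)
print("retained homologs:", [h.subject_id for h in retained])

rng = np.random.default_rng(0)
upstream = "".join(rng.choice(list("ACGT"), 250))
motif = "CATGGC"
# plant the motif so its 3' end sits 167 bp upstream of the ATG
i = 250 - 167 + 1 - len(motif)
flank = upstream[:i] + motif + upstream[i + len(motif):] + "ATGGCTGAA"
for hit in scan_tsd(SequenceRecord("flank", flank), motif, start_codon_pos=250):
    print(f"TSD motif at flank[{hit.start}:{hit.end}], "
          f"{hit.distance_upstream} bp upstream of the start codon")
# distances are 1-based bp from the motif's 3' end to the base immediately
# 5' of the ATG, the convention used for reporting TSD remnants.
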