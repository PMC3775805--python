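"""Distance statistics over a cross-link database table.

Reads a synthetic stand-in for a literature-curated DSS/BS3 cross-link
compilation (506 intra- + 62 inter-protein links from 14 publications) and
derives the quantities that calibrate virtual cross-link sampling: the
fraction of links within the 34 A ruler and the five bin probabilities.
"""

from xlmod.synthetic_fixtures import make_xldb_table
from xlmod.xldb_stats import (bin_probabilities, count_by_type,
                              count_publications, ecdf, fraction_within,
                              read_xldb)

records = read_xldb(make_xldb_table(seed=0))
counts = count_by_type(records)
print(f"records: {len(records)}  intra {counts['intra']}, inter {counts['inter']}"
      f"  from {count_publications(records)} publications")

sasd = [r.sasd for r in records]
print(f"fraction of SAS distances <= 34 A: {100 * fraction_within(sasd):.1f}%")

dist = bin_probabilities(sasd)
for b in range(dist.n_bins):
    print(f"  bin {dist.edges[b]:4.0f} - {dist.edges[b + 1]:4.0f} A : "
          f"{100 * dist.probabilities[b]:5.1f}%")

f = ecdf(sasd)
for x in (10, 20, 30, 34):
    print(f"ECDF({x} A) = {float(f(x)):.3f}")
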