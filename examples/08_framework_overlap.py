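"""Overlap and novelty statistics against established resilience frameworks.

The packaged table maps 39 indicators to the Community Resilience Index,
the PEOPLES framework and the Sendai framework, plus a novelty flag.  The
counts below are pure column sums over that table.
"""

import json

from resilmine.frameworks import load_membership, overlap_stats

table = load_membership()
stats = overlap_stats(table)
print(f"indicators: {stats['n_indicators']}")
for name, s in stats["frameworks"].items():
    print(f"  present in {name:8s}: {s['count']:2d} ({s['fraction']:.0%})")
print(f"  flagged novel     : {stats['novel']['count']:2d} ({stats['novel']['fraction']:.0%})")
print(f"\nrows both framework-present and novel ({len(stats['novel_and_present'])}):")
for name in stats["novel_and_present"]:
    print(f"  - {name}")
print("\nCounts come from the table itself; rows carrying both flags are")
print("surfaced rather than reconciled.")
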