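"""Resolve miRNA-target evidence levels with the consensus rule.

Builds three candidate interactions by hand and shows how experimental
flags and multi-tool predictions resolve to levels 1-3 (or rejection).
"""

from glunet.mti import MTIEvidence, PredictionHit, consensus_accept, evidence_level

candidates = [
    MTIEvidence("miR-375", "Pdk1", experimental_strong=True),
    MTIEvidence(
        "miR-146b",
        "Crem",
        hits={
            "miranda": PredictionHit("miranda", 152.0, -16.2),
            "pita": PredictionHit("pita", 88.0, -12.4),
            "rnahybrid": PredictionHit("rnahybrid", 120.0, -18.9),
        },
    ),
    MTIEvidence(  # only two tools: fails the >= 3-tool consensus
        "miR-16", "Txnip",
        hits={
            "pita": PredictionHit("pita", 95.0, -14.0),
            "targetscan": PredictionHit("targetscan", 0.9, -11.0),
        },
    ),
]

for e in candidates:
    level = evidence_level(e)
    verdict = f"level {level}" if level else "rejected"
    print(f"{e.mirna} -> {e.gene}: {len(e.hits)} tool hits, "
          f"consensus={consensus_accept(e)}, {verdict}")

# Level 1 = reporter-assay/Western-blot support, level 2 = CLIP-class,
# level 3 = consensus prediction (>= 3 tools, MFE <= -10 kcal/mol,
# miRanda score >= 140 when miRanda is a supporter).
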