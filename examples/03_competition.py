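"""Annotation competition.

Three overlapping hits from different databases compete: the longest
wins each locus unless the overlap is within the allowance; hits from
the same database stack freely (tandem repeats stay visible).
"""

from junctionscan.competition import CompetitionParams, compete
from junctionscan.homology import HomologyFeature


def hit(start, end, db, subject):
    return HomologyFeature("bac1", start, end, "+", db, subject, 1,
                           end - start, float(end - start), "blast")


features = [
    hit(0, 1450, "crm1db", "CRM1_LTR"),      # long LTR hit
    hit(1200, 1500, "crm3db", "CRM3_LTR"),   # shorter, overlaps by 250
    hit(1430, 2000, "centcdb", "CentC_sat"), # overlaps the winner by 20
    hit(1600, 1900, "centcdb", "CentC_sat"), # same-db stack (tandem)
]

track = compete(features, CompetitionParams(allowance_nt=25,
                                            db_priority=("crm1db", "crm3db",
                                                         "centcdb")))
for f in track.kept:
    print(f"kept       {f.subject_id:10s} {f.q_start + 1:>5}-{f.q_end}")
for victim, eliminator in track.eliminated:
    print(f"eliminated {victim.subject_id:10s} {victim.q_start + 1:>5}-"
          f"{victim.q_end}  (by {eliminator.subject_id})")
# The CRM3 hit loses: it overlaps the longer CRM1 hit by 250 nt, beyond
# the 25 nt allowance. The CentC hits survive — one overlaps by only
# 20 nt, and same-database hits never eliminate each other.
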