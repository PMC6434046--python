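"""Hand-constructed classification fixtures.

The bait sits on chr1 '+' with cut_pos 10_000 (see the ``bait`` fixture);
rules under test: deletions touching bases [cut-5, cut+4] or insertion
points in [cut-5, cut+5] (the symmetric 5-bp neighborhood of the cut
boundary) make an indel; a prey on the bait chromosome within
+/- 250 kb (inclusive) is a proximal rejoining (large_deletion /
inversion); anything farther or inter-chromosomal is a translocation.

Each row: (name, prey (chrom, coord, strand) or None,
edits [(op, pos, length)], expected category, expected subcategory).
"""

CUT = 10_000

FIXTURES = [
    ("no_prey_no_edits", None, [], "germline", "perfect"),
    ("substitutions_only", None, [("X", CUT, 2)], "germline", "perfect"),
    ("del_2nt_at_cut", None, [("D", CUT, 2)], "indel", "small_deletion"),
    ("ins_at_cut", None, [("I", CUT, 4)], "indel", "small_insertion"),
    ("ins_and_del_in_window", None, [("I", CUT - 1, 2), ("D", CUT + 1, 3)],
     "indel", "insertion_plus_deletion"),
    ("del_at_plus4_boundary", None, [("D", CUT + 4, 1)], "indel", "small_deletion"),
    ("del_at_plus5_outside", None, [("D", CUT + 5, 1)], "germline", "perfect"),
    ("del_at_minus5_boundary", None, [("D", CUT - 5, 1)], "indel", "small_deletion"),
    ("del_at_minus6_outside", None, [("D", CUT - 6, 1)], "germline", "perfect"),
    ("del_run_reaching_window", None, [("D", CUT - 10, 6)], "indel", "small_deletion"),
    ("del_run_stopping_short", None, [("D", CUT - 10, 5)], "germline", "perfect"),
    ("ins_at_plus5_boundary", None, [("I", CUT + 5, 1)], "indel", "small_insertion"),
    ("ins_at_plus6_outside", None, [("I", CUT + 6, 1)], "germline", "perfect"),
    ("del_far_from_cut", None, [("D", 5_000, 3)], "germline", "perfect"),
    ("prey_40kb_downstream_same_strand", ("chr1", CUT + 40_000, "+"), [],
     "indel", "large_deletion"),
    ("prey_at_250kb_boundary", ("chr1", CUT + 250_000, "+"), [],
     "indel", "large_deletion"),
    ("prey_past_250kb", ("chr1", CUT + 250_001, "+"), [],
     "translocation", "background_translocation"),
    ("prey_upstream_same_strand", ("chr1", CUT - 9_000, "+"), [],
     "indel", "large_deletion"),
    ("prey_flipped_within_span", ("chr1", CUT + 100, "-"), [],
     "indel", "inversion"),
    ("prey_flipped_far_within_span", ("chr1", CUT + 200_000, "-"), [],
     "indel", "inversion"),
    ("prey_other_chromosome", ("chr2", 500_000, "+"), [],
     "translocation", "background_translocation"),
    ("prey_other_chromosome_minus", ("chr2", 500_000, "-"), [],
     "translocation", "background_translocation"),
    ("prey_rule_beats_window_edits", ("chr1", CUT + 40_000, "+"), [("D", CUT, 2)],
     "indel", "large_deletion"),
    ("translocation_with_window_edits", ("chr2", 750_000, "+"), [("D", CUT, 1)],
     "translocation", "background_translocation"),
]
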