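# Packaged flow specification for the synthetic audit fixture.
#
# The plan realizes the published screening/matching accounting exactly:
# 779 retrieved; 318 excluded at the direct-funding screen (the per-reason
# split below is fixed by this spec — the published flow pins only the
# total); Sample 1 = 461; 72 excluded for non-participating subsidiaries,
# Sample 2 = 389; cohort exclusions 72+30+18+10 = 130 leaving a 331-study /
# 907-author transparency cohort; a 218-name disclosure list with 42 planted
# correspondences; 152 articles / 527 authors untouched by any match, with
# 131 distinct corresponding authors surveyed (14/29/68/20 outcomes).
seed: 640531
n_total: 779
exclusion_plan:
  ci_only: 200
  indirect: 60
  other_cola: 30
  indexing_error: 28
subsidiary_plan: 72
cohort_plan:
  pre_window: 30
  post_window: 18
  consortium: 10
  non_pi: 0
roster_plan:
  cohort_authors: 907
  planted_matches: 42
  disclosure_size: 218
  unmatched_articles: 152
  unmatched_authors: 527
  unmatched_corresponding: 131
survey_plan:
  confirmed: 14
  denied: 29
  no_reply: 68
  invalid_address: 20
topic_plan:
  k: 6
  vocab_size: 240
  doc_length: 80
  concentration: 0.2
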