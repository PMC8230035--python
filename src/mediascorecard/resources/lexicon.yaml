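# Default criterion lexicon shipped with mediascorecard.
#
# These term lists are this package's own, versioned detection vocabulary,
# seeded from the worked phrases the scorecard rubric prints and expanded
# conservatively. Entries are lowercase; matching is case-insensitive and
# token-boundary anchored. Edit freely, bump the version, and reports will
# record which lexicon produced them.
version: "2026.09-1"

# corpus prefilter: phrases that flag an article as possibly suicide-related
prefilter_keywords:
  - suicide
  - kills self
  - ends life

# terms marking a sentence as being about the suicide case itself
# (drives the "at least half the content" relevance fraction)
case_terms:
  - suicide
  - suicides
  - kills self
  - ends life
  - ended his life
  - ended her life
  - took his own life
  - took her own life
  - killed himself
  - killed herself
  - died by suicide
  - death by suicide
  - attempted suicide
  - suicide attempt

# N1 — language framing suicide as a crime or sin
criminalizing_phrases:
  - committed suicide
  - commit suicide
  - commits suicide
  - committing suicide
  - crime of suicide
  - sin of suicide

# N3 — suicide methods
method_terms:
  - hanging
  - hanged
  - poison
  - poisoning
  - pesticide
  - overdose
  - jumped
  - jumping
  - drowned
  - drowning
  - self-immolation
  - immolated
  - shot himself
  - shot herself
  - electrocuted

# N4 — specific objects/substances; two distinct terms = detailed description
method_detail_terms:
  - nylon rope
  - ceiling fan
  - kerosene
  - celphos tablets
  - sleeping pills
  - organophosphate
  - dupatta
  - bedsheet
  - razor blade
  - railway track

# N5 — identifiable, publicly accessible locations
site_terms:
  - railway bridge
  - city reservoir
  - clock tower
  - water tank near
  - terrace of the apartment
  - hostel room number

# N6 — assertions of a single cause, and the speculation cues that negate them
single_factor_markers:
  - the only reason
  - solely because
  - driven to suicide by
  - attributed the suicide to
  - the sole trigger
speculation_markers:
  - the reason may be
  - uncertainties about the cause remain
  - reasons are not yet known
  - it is suspected that
  - possibly due to

# P1 — crisis-support services; names must match the helpline registry for P2
helpline_names:
  - sneha suicide prevention centre
  - icall helpline
  - aasra helpline
  - vandrevala foundation helpline
  - kiran helpline
helpline_phone_patterns:
  - '\b1800[- ]?\d{3}[- ]?\d{4}\b'
  - '\b0\d{2,4}[- ]\d{6,8}\b'

# P3 — mental-health linkage: clinical terms accepted, loose qualifiers rejected
mental_health_accept_terms:
  - depressed
  - depression
  - anxious
  - anxiety
  - panic
  - trauma
  - disturbed
  - distraught
  - bipolar disorder
  - schizophrenia
  - post-traumatic stress
mental_health_reject_terms:
  - crazy
  - mental
  - stressed
  - unhappy
  - upset

# P4 — ongoing substance struggle qualifies; intoxication at the time does not
substance_struggle_terms:
  - alcohol addiction
  - drug addiction
  - alcoholism
  - substance abuse
  - drug dependence
  - struggled with alcohol
  - struggled with drugs
intoxication_only_terms:
  - drunk at the time
  - intoxicated state
  - under the influence of alcohol
  - inebriated

# P5 — expert comment requires a professional role plus an attribution verb
expert_role_terms:
  - psychiatrist
  - psychologist
  - mental health professional
  - suicide prevention expert
  - counsellor
attribution_verbs:
  - said
  - stated
  - told
  - confirmed
  - according to
  - noted
  - added

# P10 — named official sources qualify; bare "sources" does not
official_source_terms:
  - police officers
  - police said
  - the police confirmed
  - superintendent of police
  - health department officials
  - district collector
  - government authority
  - hospital authorities
  - healthcare professionals
bare_source_phrases:
  - according to sources
  - sources said
  - sources told

# P7 — population-level statistics (a digit must co-occur in the sentence)
stat_markers:
  - per 100,000
  - suicide rate
  - deaths by suicide were recorded
  - national crime records bureau
  - percent of suicides
  - cases of suicide were reported

# P6 — prevention / stigma-reduction messaging
prevention_markers:
  - suicides are preventable
  - suicide is preventable
  - seeking help
  - reducing stigma
  - warning signs can be identified
  - timely intervention

# P8 — myth challenged with an explicit refutation in the same sentence
myth_markers:
  - myth
  - misconception
  - contrary to popular belief
  - it is widely believed
refutation_markers:
  - "false"
  - untrue
  - not true
  - debunked
  - evidence shows

# P9 — recovery / coping narratives
hope_markers:
  - overcame suicidal thoughts
  - recovered from a suicide attempt
  - found hope
  - rebuilt his life
  - rebuilt her life
  - survivor of a suicide attempt

# N8 — bereaved persons
grief_terms:
  - bereaved
  - grieving family
  - grieving relatives
  - mourning
  - inconsolable
  - family members wept

# N9 — published notes / final messages (requires quoted text in the body)
note_terms:
  - suicide note
  - left a note
  - note recovered
  - final message
  - farewell message

# N2 — attention-grabbing headline: "suicide", a method, or a reason
# (reason = cue word + stressor noun, both in the headline)
reason_cues:
  - after
  - over
  - due to
  - following
reason_stressors:
  - exam
  - exams
  - debt
  - loan
  - harassment
  - failure
  - breakup
  - dowry
  - unemployment
  - illness
  - losses
  - scolding

# screening fallback cues (heuristic; a manual category tag always wins)
commentary_cues:
  - editorial
  - opinion piece
  - commentary on
ideation_cues:
  - suicidal ideation
bombing_cues:
  - suicide bomber
  - suicide bombing
  - suicide attack
  - blew himself up
  - blew herself up
undetermined_cues:
  - could be a suicide or
  - whether it was suicide or murder
  - yet to be ascertained
  - death under mysterious circumstances
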