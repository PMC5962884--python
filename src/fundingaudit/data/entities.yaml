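# Funder-entity dictionary: canonical names, printed variants, brand groups.
# Groups: parent_company / foundation / institute_bihw / north_america are
# the US brand core; subsidiary_participating are affiliates that published
# transparency lists; subsidiary_nonparticipating did not; other_cola are
# unrelated same-name brands the broad text search also catches.
entities:
  - canonical_name: The Coca-Cola Company
    group: parent_company
    variants:
      - The Coca-Cola Company
      - Coca-Cola Company
      - Coca-Cola
      - Coca Cola
  - canonical_name: The Coca-Cola Foundation
    group: foundation
    variants:
      - The Coca-Cola Foundation
      - Coca-Cola Foundation
  - canonical_name: Coca-Cola North America
    group: north_america
    variants:
      - Coca-Cola North America
  - canonical_name: Beverage Institute for Health and Wellness
    group: institute_bihw
    variants:
      - Beverage Institute for Health and Wellness
      - The Beverage Institute of Health and Wellness
      - Beverage Institute of Health and Wellness
  - canonical_name: Coca-Cola South Pacific
    group: subsidiary_participating
    variants:
      - Coca-Cola South Pacific
  - canonical_name: Coca-Cola Australia Foundation
    group: subsidiary_participating
    variants:
      - Coca-Cola Australia Foundation
  - canonical_name: Coca-Cola Oceania
    group: subsidiary_participating
    variants:
      - Coca-Cola Oceania
  - canonical_name: Coca-Cola Germany
    group: subsidiary_participating
    variants:
      - Coca-Cola Germany
      - Coca-Cola GmbH
  - canonical_name: Coca-Cola Spain
    group: subsidiary_participating
    variants:
      - Coca-Cola Spain
      - Coca-Cola Iberia
  - canonical_name: Coca-Cola France
    group: subsidiary_participating
    variants:
      - Coca-Cola France
  - canonical_name: Coca-Cola Brasil
    group: subsidiary_nonparticipating
    variants:
      - Coca-Cola Brasil
      - Coca-Cola Brazil
  - canonical_name: Coca-Cola Hellas
    group: subsidiary_nonparticipating
    variants:
      - Coca-Cola Hellas
  - canonical_name: Coca-Cola Japan
    group: subsidiary_nonparticipating
    variants:
      - Coca-Cola Japan
  - canonical_name: Coca-Cola India
    group: subsidiary_nonparticipating
    variants:
      - Coca-Cola India
  - canonical_name: Pepsi-Cola
    group: other_cola
    variants:
      - Pepsi-Cola
      - PepsiCo
  - canonical_name: RC Cola
    group: other_cola
    variants:
      - RC Cola
      - Royal Crown Cola
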