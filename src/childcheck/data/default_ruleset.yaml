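# Default lifestyle ruleset (editable placeholders).
#
# Levels echo common public-health guidance for school-age children; they
# are configuration, not clinical authority. Messages are string.Template
# texts with $reported, $recommended, $units and $behaviour placeholders.
rules:
  - behaviour_id: fruit_veg_portions
    label: fruit and vegetables
    comparator: at_least
    recommended_level: 5
    units: portions/day
    encouragement_text: >-
      Well done - $reported portions of fruit and vegetables a day meets the
      recommended $recommended. Keep it up!
    advice_text: >-
      Aim for at least $recommended portions of fruit and vegetables a day
      (currently $reported). Try adding fruit to breakfast and a vegetable to
      every main meal.
  - behaviour_id: mvpa_minutes
    label: moderate-to-vigorous physical activity
    comparator: at_least
    recommended_level: 60
    units: min/day
    encouragement_text: >-
      Great - $reported minutes of activity a day meets the recommended
      $recommended minutes.
    advice_text: >-
      Aim for at least $recommended minutes of moderate-to-vigorous activity a
      day (currently $reported). Walking or cycling to school and active games
      all count.
  - behaviour_id: screen_hours
    label: recreational screen time
    comparator: at_most
    recommended_level: 2
    units: h/day
    encouragement_text: >-
      Well done - $reported hours of screen time a day is within the
      recommended limit of $recommended hours.
    advice_text: >-
      Try to keep recreational screen time to at most $recommended hours a day
      (currently $reported). Agree screen-free times, especially before bed.
  - behaviour_id: sugary_drinks
    label: sugary drinks
    comparator: at_most
    recommended_level: 1
    units: drinks/day
    encouragement_text: >-
      Well done - $reported sugary drinks a day is within the recommended
      limit of $recommended.
    advice_text: >-
      Cut sugary drinks to at most $recommended a day (currently $reported).
      Swap for water or milk; many juices contain more sugar than they seem to.
  - behaviour_id: sleep_hours
    label: sleep
    comparator: at_least
    units: h/night
    age_bands:
      - {min_age: 5, max_age: 6, level: 10.5}
      - {min_age: 6, max_age: 12, level: 9.5}
      - {min_age: 12, max_age: 18, level: 8.5}
    encouragement_text: >-
      Good - $reported hours of sleep a night meets the recommended
      $recommended hours for this age.
    advice_text: >-
      Aim for at least $recommended hours of sleep a night (currently
      $reported). A regular bedtime and no screens in the bedroom help.
  - behaviour_id: breakfast_days
    label: breakfast
    comparator: at_least
    recommended_level: 7
    units: days/week
    encouragement_text: >-
      Great - eating breakfast $reported days a week meets the recommended
      daily breakfast habit.
    advice_text: >-
      Aim to eat breakfast every day (currently $reported days/week). Choose
      low-sugar cereals or wholemeal toast.
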