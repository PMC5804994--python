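# Canonical 17-parameter sleep-scenario space.
#
# 16 parameters carry 3 options; "wake after sleep onset" carries 5.
# Level 1 is the first option listed and serves as the reference level
# throughout the package (indices are 1-based).
#
# Note: the source instrument lists "I felt very uncomfortable" for both the
# first and third option of physiological arousal, an apparent transcription
# error; the third option here is "I felt very comfortable", consistent with
# the instrument's own exemplar narrative of a preferred night of sleep.
parameters:
  - name: amount_of_activity
    period: day_before
    levels:
      - "I did little"
      - "I did an average amount"
      - "I did a lot"
  - name: day_went_well
    period: day_before
    levels:
      - "Did not go so well"
      - "Went OK"
      - "Went well"
  - name: mood_day_before
    period: day_before
    levels:
      - "I felt rubbish"
      - "I felt alright"
      - "I felt positive"
  - name: readiness_to_sleep
    period: pre_sleep
    levels:
      - "I did not feel sleepy at all"
      - "I felt moderately sleepy"
      - "I felt very sleepy"
  - name: cognitive_arousal
    period: pre_sleep
    levels:
      - "My mind was racing with thoughts"
      - "My mind was wandering with thoughts"
      - "My mind was blank"
  - name: physiological_arousal
    period: pre_sleep
    levels:
      - "I felt very uncomfortable"
      - "I felt not so uncomfortable"
      - "I felt very comfortable"
  - name: sleep_onset_latency
    period: during_sleep
    levels:
      - "It took me a long time"
      - "It took me a short while"
      - "It took me no time"
  - name: wake_after_sleep_onset
    period: during_sleep
    levels:
      - "I woke up in the middle of the night and was unable to fall back to sleep"
      - "I woke up in the middle of the night and was eventually able to fall back to sleep"
      - "I woke a number of times but only briefly"
      - "I woke once or twice but only briefly"
      - "I slept through the night"
  - name: total_sleep_time
    period: during_sleep
    levels:
      - "I think I slept for 9.5 hours"
      - "I think I slept for 7.5 hours"
      - "I think I slept for 5.5 hours"
  - name: dream
    period: during_sleep
    levels:
      - "I remember having many dreams"
      - "I remember I dreamt"
      - "I don't remember any dreams"
  - name: feeling_refreshed
    period: upon_waking
    levels:
      - "I felt unrefreshed"
      - "I felt somewhat refreshed"
      - "I felt refreshed"
  - name: motivated_to_get_up
    period: upon_waking
    levels:
      - "I felt unmotivated"
      - "I felt somewhat motivated"
      - "I felt motivated"
  - name: alertness
    period: day_after
    levels:
      - "I felt drowsy"
      - "I felt tired"
      - "I felt alert"
  - name: thinking
    period: day_after
    levels:
      - "My head felt cloudy"
      - "My head was reasonably clear"
      - "My head was clear"
  - name: mood_day_after
    period: day_after
    levels:
      - "My mood was bad"
      - "My mood was average"
      - "My mood was good"
  - name: sociability
    period: day_after
    levels:
      - "I was antisocial"
      - "I was somewhat sociable"
      - "I was sociable"
  - name: physical_activity
    period: day_after
    levels:
      - "I was sluggish"
      - "I was reasonably active"
      - "I was active"
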