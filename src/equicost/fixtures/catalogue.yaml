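# Default service catalogue for township health centers.
#
# The essential-public-health side lists 13 categories totalling 37 items.
# Item-level names within each category are plausible sub-services chosen by
# this package (only the category names and the 13/37 totals are fixed by the
# study design); the per-category item counts are an assumption.
#
# The primary-medical side is only ever used at category granularity, so its
# 71 items are numbered placeholders with a configurable count per category.
service_classes:
  nephsp:
    categories:
      - name: establishment of resident health records
        items:
          - creation of resident health record
          - update and maintenance of resident health record
          - electronic record entry and verification
      - name: health education
        items:
          - distribution of printed health education materials
          - health education bulletin board updates
          - public health consultation events
          - health knowledge lectures
          - individualised health education
          - audio-visual health education sessions
      - name: preventive inoculation
        items:
          - vaccination record management
          - routine immunisation administration
          - adverse event observation and reporting
      - name: children health management
        items:
          - newborn home visit
          - newborn full examination
          - infant health check (0-3 years)
          - preschool child health check (4-6 years)
      - name: maternal health management
        items:
          - first-trimester registration and examination
          - second-trimester follow-up
          - third-trimester follow-up
          - postpartum home visit
          - postpartum 42-day examination
      - name: elderly health management
        items:
          - annual elderly health examination
          - elderly lifestyle and health assessment
      - name: chronic disease management (hypertension)
        items:
          - hypertension screening
          - hypertension quarterly follow-up
          - hypertension annual examination
      - name: chronic disease management (type 2 diabetes)
        items:
          - diabetes screening
          - diabetes quarterly follow-up
          - diabetes annual examination
      - name: severe mental disorder management
        items:
          - severe mental disorder patient registration
          - severe mental disorder follow-up assessment
      - name: tuberculosis patient management
        items:
          - tuberculosis case screening and referral
          - tuberculosis supervised medication follow-up
      - name: traditional Chinese medicine health management
        items:
          - TCM constitution identification for the elderly
          - TCM health guidance for children
      - name: reporting and management of infectious diseases and public health emergencies
        items:
          - infectious disease and emergency event reporting
      - name: supervision and co-management of health and family planning
        items:
          - health supervision inspection and co-management visit
  primary_medical:
    categories:
      - name: clinical medical services
        n_placeholder_items: 25
      - name: nursing services
        n_placeholder_items: 15
      - name: pharmaceutical services
        n_placeholder_items: 10
      - name: medical technology services
        n_placeholder_items: 12
      - name: public health support services
        n_placeholder_items: 9
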