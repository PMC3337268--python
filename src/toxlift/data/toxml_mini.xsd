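<?xml version="1.0"?>
<!-- Miniature ToxML-style schema: nested study structure, Tests/Compounds
     container wrappers, an ambiguous Results field used in two contexts,
     a Sex enumeration, and a ChronicStudies element for the IS-A example. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="ToxML">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Study" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Background">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="ReferenceCompound">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="Name" type="xs:string"/>
                          <xs:element name="CASNumber" type="xs:string"/>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="StudyType" type="xs:string"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="Tests">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Test" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="TestAnimal">
                            <xs:complexType>
                              <xs:sequence>
                                <xs:element name="Species" type="xs:string"/>
                                <xs:element name="Sex">
                                  <xs:simpleType>
                                    <xs:restriction base="xs:string">
                                      <xs:enumeration value="male"/>
                                      <xs:enumeration value="female"/>
                                    </xs:restriction>
                                  </xs:simpleType>
                                </xs:element>
                              </xs:sequence>
                            </xs:complexType>
                          </xs:element>
                          <xs:element name="TreatmentGroup" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:sequence>
                                <xs:element name="Dose" type="xs:decimal"/>
                                <xs:element name="Results">
                                  <xs:complexType>
                                    <xs:sequence>
                                      <xs:element name="SurvivalRate" type="xs:string"/>
                                    </xs:sequence>
                                  </xs:complexType>
                                </xs:element>
                              </xs:sequence>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="Compounds">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Compound" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="Name" type="xs:string"/>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="Results">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Summary" type="xs:string"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="ChronicStudies">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="DurationWeeks" type="xs:integer"/>
              <xs:element name="Tests">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Test" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="TestAnimal">
                            <xs:complexType>
                              <xs:sequence>
                                <xs:element name="Species" type="xs:string"/>
                              </xs:sequence>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
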